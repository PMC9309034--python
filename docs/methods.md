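# Methods

This note records the statistical model behind each stage, the defaults
and why they were chosen, the numerical conventions, and what the
synthetic data do and do not establish.

## Detections

A camera records bursts of images; the unit of analysis is the
*independent detection*: within one (site, species) stream ordered by
time, a new detection starts when the gap from the previous image exceeds
`gap_minutes` (default 15; a gap of exactly 15 min continues the event).
The rule chains, so a detection can span more than 15 min in total —
standard camera-trap practice.  The detection carries the first image's
timestamp, and streams run in continuous calendar time, so detections may
span midnight.

Deer group composition within a detection uses per-image maxima of the
class counts, so one fawn anywhere in the burst makes the detection a
nursery group.  How counts should be reconciled across a burst's images
is genuinely open; maxima match the "any fawn present" definition of a
nursery group and are the default (the counts are kept per event, so a
different reduction can be applied upstream).  Classification priority is
fawn ⇒ nursery group, else adult female, else adult male; all-zero deer
detections are flagged excluded rather than erroring.

Times are local standard clock times mapped to angles; no solar-time
transformation is applied (activity relative to sunrise/sunset can be
obtained by annotating externally).

## Circular kernel density estimation

The density estimate is the exact kernel mean
f̂(θ) = (1/n) Σᵢ K(θ; tᵢ, κ) with the von Mises kernel
K(θ; μ, κ) = exp(κ cos(θ−μ))/(2π I₀(κ)), evaluated with exponentially
scaled Bessel functions so concentrations up to ~10³ stay finite.
Overlap estimation evaluates the same kernel sum at arbitrary data points
(never grid interpolation); the 512-point grid at angles 2πk/512 exists
only for tabulation, plotting and Δ̂₁.

**Bandwidth.**  `kappa="auto"` uses a Taylor-type plug-in: a pilot von
Mises concentration k̂ and then
ν = (3 n k̂² I₂(2k̂) / (4√π I₀(k̂)²))^{2/5} · adjust (default adjust = 1,
configurable as `bw_adjust`).  The pilot is the larger of the
concentrations implied by the first and second trigonometric moments
(solving I_m(κ)/I₀(κ) = R̄_m).  For a true von Mises the two moments give
the same κ, so the unimodal case is unaffected; for bimodal diel shapes —
the crepuscular dawn/dusk pattern typical of deer — the first moment
nearly cancels and a first-moment-only pilot over-smooths badly, while
the second moment still sees the peak sharpness.  In oracle checks
against exact mixture overlap this kept Δ̂₄ errors within ±0.02 at
n = 2000 across random one- to three-component mixtures.  Every fit
records the κ used (`kappa_`) and the unimodal ML estimate
(`kappa_mle_`).

Samples below n = 75 trigger a warning (the conventional reliability
floor for Δ̂₄), not a failure.  Fits require n ≥ 2.

## Overlap coefficients

Δ = ∫ min(f₁, f₂) dθ is estimated by:

* **Δ̂₄** (default): ½ [ mean_i min(f̂₂(x₁ᵢ)/f̂₁(x₁ᵢ), 1) +
  mean_j min(f̂₁(x₂ⱼ)/f̂₂(x₂ⱼ), 1) ].  Estimated densities are floored at
  1e-12 inside the ratios so an empty region cannot divide by zero.
* **Δ̂₁**: trapezoidal integral of min(f̂₁, f̂₂) over the closed grid;
  automatically substituted (with a logged notice) when
  min(n₁, n₂) < 75.

Both samples use identical kernel *settings*; the automatic bandwidth is
still selected per sample because it is data-driven, and for the same
reason the bootstrap re-selects it inside every replicate.

**Confidence limits** are a percentile bootstrap (B = 1000 default,
minimum 100) with both samples resampled independently; the percentile
interval is re-centered on the point estimate (shifted by
Δ̂ − mean of replicates, clipped to [0, 1]).  Raw percentile intervals
are biased low near the Δ = 1 boundary — two independent resamples of
the same sample never overlap perfectly — and re-centering is the usual
correction for overlap coefficients.

**Equality test**: both samples are pooled and `n_perm` (default 999,
minimum 99) pseudo-sample pairs of the original sizes are drawn from the
pool with replacement; p = (1 + #{Δ̂_perm ≤ Δ̂_obs})/(1 + n_perm),
one-sided in the low-overlap direction (low observed overlap is the
evidence against equality).  Under the null the test is conservative to
nominal (measured rejection ≤ 15% at α = 0.05 over seeded repetitions).

## Competing-risks cumulative incidence

Monitoring is on a daily grid: day 0 is the first study day and an animal
that dies on day t contributes a cause-k event at t.  The Aalen–Johansen
recursion (daily steps) is

    S(t)     = S(t−1) · (1 − Σ_k d_k(t)/n(t))
    CIF_k(t) = CIF_k(t−1) + S(t−1) · d_k(t)/n(t)

with n(t) the number under observation during (t−1, t].  Ties between a
death and a censoring on the same day keep the censored animal in that
day's risk set (events before censorings) — the common convention; it is
not identifiable from data and is implemented in one place should a user
need the opposite order.  Staggered entry is supported structurally
(`start_day`) but cohorts built here all start at day 0.  Variance
estimation is omitted; the estimator is reported as point curves.  When
every death has a typed cause, S(t) + Σ_k CIF_k(t) = 1 holds to 1e-12 by
construction and is tested.

The default horizon is day 77 (a July 15 – September 30 season); the
synthetic cohorts use 78 daily steps, matching their closed-form
calibration CIF_k(t) = (h_k/h_tot)(1 − (1 − h_tot)^t).

## Risk weights and the diel risk index

Only mortality sources with an observable diel activity can enter the
index: the four carnivores and humans (vehicle collisions are the human
cause and map to human activity).  Weights are the identified-cause CIFs
renormalized to sum to 1; unidentified predation, disease and unknown
causes are reported as `excluded_mass` and otherwise dropped (they have
no activity density to weight).  A pro-rata redistribution of
unidentified predation over the carnivores was considered and rejected as
the default — it asserts information the data do not contain — but the
weights function accepts any cause→CIF map, so it is a one-liner
upstream.

The index is index(θ) = Σ_k w_k f̂_k(θ) with per-source components kept
for stacked-area display.  It is not renormalized: the weights sum to 1
and each density integrates to 1, so the index already integrates to 1.

The moving-window series estimates, for each day from July 20 to
September 10, the overlap between deer and pooled carnivore detections
dated within ±5 days (an 11-day window, boundaries inclusive).  Pooling
the four carnivore species into one sample (rather than averaging four
densities) weights species by detection frequency, which is what a
single-sample density fit would see; windows with fewer than `min_n = 20`
detections on either side are reported missing with their counts.  The
estimator follows the global Δ̂₄/Δ̂₁ floor-of-75 substitution per window.

Reported percentages (relative overlap changes, group averages) round
half away from zero to integer percent.

## Synthetic data

Detection times are von Mises mixtures: nocturnal carnivores (means near
midnight, κ ≈ 1.2–2.5, bears and wolves with a secondary early-morning
component), diurnal humans (mean 13:00, κ = 3), crepuscular adult deer
(dawn ≈ 06:00 and dusk ≈ 20:30 peaks, κ = 3), and nursery groups with a
third daytime component shifting mass into daylight.  Default counts per
species match field-scale camera seasons (356 bobcat to 27 228 human
detections); `scale` shrinks them for quick runs.  Dates are uniform over
a July 15 – September 15 season — the generator has no seasonal trend, so
a flat moving-window series is the correct expectation against which the
window machinery is checked.

Cohorts use constant daily cause-specific hazards and daily censoring
(geometric-type event days, matching the daily-step estimator).  Fawn
hazards are calibrated so the analytic terminal CIFs are bear 0.01,
bobcat 0.02, coyote 0.04, wolf 0.01, vehicle 0.03, unidentified predation
0.04, disease 0.01 (total 0.16, with 232 fawns and censoring matched to
~15 collar losses); adult cohorts (437 + 108) total 0.03 split
coyote/wolf/vehicle in proportion 0.15/0.46/0.38.  Ground truth
(mixture components, hazards, analytic CIFs) travels with every bundle.

What passing recovery tests shows: the estimators are consistent for the
model they assume — independent detections from a stationary mixture,
constant hazards, independent censoring.  Real data violate all three in
ways the generator deliberately does not emulate (detection
non-independence beyond the 15-min rule, seasonal activity shifts,
age-varying hazards), so recovery here validates the computation, not the
field design.

## Problem sizes and determinism

The test suite and the acceptance script run the generator at reduced
detection scale (3–10% of field-scale counts) and full cohort sizes;
oracle checks use n = 2000 per sample for overlap (10 mixture pairs) and
50 random micro-cohorts for the cumulative-incidence recursion.  The
acceptance script averages total-mortality estimates over 20 replicate
cohorts to separate estimator bias from single-cohort Monte-Carlo noise.
Every stochastic step takes an explicit seed (numpy `default_rng`);
reruns with the same config and seed are bit-identical, which the suite
asserts.

## Known limitations

* Activity *level* (proportion of time active) is out of scope; densities
  integrate to 1 by construction, so the index measures timing, not
  volume, of risk.
* The bootstrap CI is a re-centered percentile interval; BCa or smoothed
  variants are not implemented.
* No spatial structure: site effects, detection-probability modelling and
  camera-array design questions are outside the package.
* The randomization test resamples from the pooled data with replacement;
  it tests distribution equality, not any parametric hypothesis.
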