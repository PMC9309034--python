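# dielrisk

Tools for asking how prey schedule their day around the mortality risks
they face.  In multi-predator systems, different demographic groups of the
same prey species — for white-tailed deer, nursery groups with fawns
versus lone adults — can shift their 24-hour (diel) activity to avoid the
times of day when their most dangerous predators are active.  `dielrisk`
links two data streams that wildlife studies routinely collect:

* **camera-trap detections** of prey, carnivores and humans, giving each
  species a diel activity density; and
* **radio-telemetry mortality records** of collared animals, giving
  cause-specific death rates under competing risks,

and combines them into mortality-weighted measures of when, over the
24-hour cycle, an animal is actually at risk.

## What it computes

**Diel activity densities.**  Time of day is an angle
θ = 2π·(seconds since midnight)/86400, and activity is a density on the
circle estimated with a von Mises kernel,
f̂(θ) = (1/n) Σᵢ exp(κ cos(θ − tᵢ)) / (2π I₀(κ)), with the concentration
κ (inverse bandwidth) chosen by a plug-in rule robust to the bimodal
(crepuscular) shapes ungulate activity takes.  Raw camera images are
first collapsed into independent detections (images of one species at one
site within 15 min of each other count once) and deer detections are
classified: any fawn present ⇒ nursery group, else adult female / adult
male.

**Temporal overlap.**  Between two groups, Δ = ∫ min(f₁, f₂) dθ ∈ [0, 1].
The Δ̂₄ estimator averages clipped density ratios at both samples' observed
points; Δ̂₁ (a grid integral) substitutes for small samples.  Uncertainty
comes from a nonparametric bootstrap; equality of two activity
distributions is tested by randomization against pooled resampling.

**Cause-specific mortality.**  Survival of a monitored cohort is tracked
on a daily grid with the Aalen–Johansen estimator: with n(t) at risk and
d_k(t) deaths of cause k on day t,
CIF_k(t) = CIF_k(t−1) + S(t−1)·d_k(t)/n(t), which handles right-censoring
and competing causes and reduces to an empirical proportion when neither
is present.

**The diel risk index.**  Each identified mortality source (four
carnivores; humans, via vehicle collisions) gets a weight equal to its
share of identified mortality, and the index is the weighted sum of the
sources' activity densities — a density showing at what times of day the
mortality an animal actually experiences is concentrated.  A daily 11-day
moving-window overlap series tracks how deer–carnivore overlap changes
through the season.

A synthetic-data generator produces detection tables (von Mises mixture
diel patterns) and mortality cohorts (daily competing hazards) with known
ground truth, so the full chain is testable end to end and parameter
recovery can be demonstrated.

## Worked example

```python
import warnings; warnings.simplefilter("ignore")
from dielrisk import (study_scenario, to_circular_times, bootstrap_overlap,
                      aalen_johansen, mortality_summary, compute_risk_weights)

bundle = study_scenario(seed=42, scale=0.1)   # synthetic field season
deer = to_circular_times(bundle.detections, group="nursery_group")
coyote = to_circular_times(bundle.detections, species="coyote")
est = bootstrap_overlap(deer, coyote, method="delta4", n_boot=200, seed=42)
print(f"nursery-coyote overlap: {est.delta:.2f} "
      f"(95% CI {est.ci_low:.2f}-{est.ci_high:.2f}, n={est.n1}/{est.n2})")

fit = aalen_johansen(bundle.mortality, stratum="fawn", horizon=78)
print(f"fawn total mortality: {mortality_summary(fit)['total']:.3f}")
weights = compute_risk_weights(fit.terminal_cif(), stratum="fawn")
print("fawn risk weights:", {k: round(v, 2) for k, v in weights.weights.items()})
```

prints

```
nursery-coyote overlap: 0.39 (95% CI 0.33-0.45, n=360/278)
fawn total mortality: 0.131
fawn risk weights: {'black_bear': 0.11, 'bobcat': 0.1, 'coyote': 0.53, 'wolf': 0.0, 'human': 0.26}
```

The overlap of 0.39 says nursery groups and coyotes share little of the
diel cycle (nocturnal coyotes vs diurnally shifted nursery groups).  The
cohort of 232 synthetic fawns was generated with a true season-long
mortality of 0.16; the estimate 0.131 is within the Monte-Carlo noise of
a cohort that size.  The risk weights are each cause's share of the
identified mortality and become the coefficients of the combined diel
risk index.

The same stages are available from a shell:

```bash
dielrisk synth --seed 42 --scale 0.1 --out-dir data/
dielrisk collapse --in data/images.csv --out data/detections.csv --gap-min 15
dielrisk overlap --a data/detections.csv:coyote --b data/detections.csv:nursery_group --boot 200 --seed 42
dielrisk cif --in data/mortality.csv --stratum fawn --horizon 78 --out data/cif.csv
dielrisk run --config analysis.yaml    # the whole chain from a YAML config
```

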