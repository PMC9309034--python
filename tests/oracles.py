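"""Independent reference implementations used only by the tests.

These deliberately avoid the package's computational paths: the overlap
truth integrates exact von Mises mixture densities on a fine grid, and the
competing-risks reference walks the day-by-day risk set with explicit
membership tests instead of vectorized accounting.
"""

import numpy as np
from scipy import special

TWO_PI = 2.0 * np.pi


def vm_pdf(theta, mu, kappa):
    return np.exp(kappa * np.cos(theta - mu)) / (TWO_PI * special.i0(kappa))


def mixture_density(components, theta):
    theta = np.asarray(theta, dtype=float)
    out = np.zeros_like(theta)
    for mu, kappa, p in components:
        out += p * vm_pdf(theta, mu, kappa)
    return out


def true_overlap_grid(components1, components2, m=200_001):
    """Delta = integral of min(f1, f2): trapezoid on a fine uniform grid."""
    grid = np.linspace(0.0, TWO_PI, m)
    lo = np.minimum(mixture_density(components1, grid),
                    mixture_density(components2, grid))
    return float(np.trapezoid(lo, grid))


def aalen_johansen_reference(histories, horizon):
    """Day-by-day product-limit recursion with explicit risk-set membership.

    ``histories``: iterable of (start_day, end_day, outcome) tuples, where
    outcome is "survived", "censored", or a cause label.  Censorings tied
    with deaths on a day remain at risk for that day's deaths.
    """
    records = [tuple(r) for r in histories]
    causes = sorted({o for _, _, o in records if o not in ("survived", "censored")})
    surv = [1.0]
    cif = {k: [0.0] for k in causes}
    for t in range(1, horizon + 1):
        at_risk = 0
        deaths = {k: 0 for k in causes}
        for s, e, o in records:
            first_day = s + 1 if e > s else max(e, 1)
            if first_day <= t <= max(e, first_day):
                at_risk += 1
                if t == max(e, first_day) and o not in ("survived", "censored"):
                    deaths[o] += 1
        d_tot = sum(deaths.values())
        for k in causes:
            inc = surv[-1] * deaths[k] / at_risk if deaths[k] else 0.0
            cif[k].append(cif[k][-1] + inc)
        surv.append(surv[-1] * (1.0 - (d_tot / at_risk if at_risk else 0.0)))
    return np.array(surv), {k: np.array(v) for k, v in cif.items()}


def random_cohort(rng, n_max=12, horizon=20):
    """A small random cohort as (DataFrame-ready dict, tuples)."""
    n = int(rng.integers(1, n_max + 1))
    causes = ["coyote", "wolf", "vehicle"]
    rows = []
    for i in range(n):
        end = int(rng.integers(1, horizon + 1))
        outcome = rng.choice(["survived", "censored"] + causes)
        if outcome == "survived":
            end = horizon
        rows.append((0, end, str(outcome)))
    return rows
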