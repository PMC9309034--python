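"""Mortality-weighted diel risk index and moving-window overlap.

Cause-specific cumulative incidence is converted to proportional risk
weights over the identified mortality sources (the four carnivores plus
human-caused vehicle mortality); unidentified predation, disease and
unknown causes carry no diel signature and are renormalized away.  The
diel risk index is then the weighted sum of the sources' activity
densities — a source causing 40% of identified mortality contributes its
activity density with weight 0.4 — so the index integrates to 1 and can
be read as the diel density of mortality risk.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .exceptions import ConfigError, EmptySelectionError, InvalidParameterError, UndefinedWeightsError
from .kde import RELIABLE_N, CircularKernelDensity
from .overlap import estimate_delta1, estimate_delta4

#: death causes whose diel activity is observable on cameras, keyed by the
#: activity source that represents them (vehicle mortality <- human activity).
CAUSE_TO_SOURCE = {
    "bear": "black_bear",
    "bobcat": "bobcat",
    "coyote": "coyote",
    "wolf": "wolf",
    "vehicle": "human",
}
IDENTIFIED_CAUSES = tuple(CAUSE_TO_SOURCE)

__all__ = [
    "RiskWeights",
    "compute_risk_weights",
    "compute_risk_index",
    "moving_window_overlap",
    "relative_overlap_change",
    "round_percent",
    "CAUSE_TO_SOURCE",
]


@dataclass(frozen=True)
class RiskWeights:
    """Proportional contribution of each identified source to mortality."""

    stratum: str | None
    weights: dict[str, float]  # activity source -> weight, sums to 1
    excluded_mass: float  # CIF mass from unidentified/disease/unknown causes


def compute_risk_weights(cause_cifs: dict[str, float],
                         identified_causes=IDENTIFIED_CAUSES,
                         stratum: str | None = None) -> RiskWeights:
    """Normalize identified-cause terminal CIFs into risk weights.

    ``w_k = CIF_k / sum over identified causes``; causes outside the
    identified set are summed into ``excluded_mass``.  Weights are keyed by
    activity source (vehicle mortality maps to human activity).
    """
    ident = {k: float(cause_cifs.get(k, 0.0)) for k in identified_causes}
    total = sum(ident.values())
    if total <= 0:
        raise UndefinedWeightsError("all identified-cause CIFs are zero")
    if any(v < 0 for v in cause_cifs.values()):
        raise InvalidParameterError("negative cumulative incidence")
    weights = {CAUSE_TO_SOURCE.get(k, k): v / total for k, v in ident.items()}
    excluded = float(
        sum(v for k, v in cause_cifs.items() if k not in identified_causes)
    )
    return RiskWeights(stratum=stratum, weights=weights, excluded_mass=excluded)


def compute_risk_index(densities: dict[str, CircularKernelDensity],
                       weights: RiskWeights) -> pd.DataFrame:
    """Weighted sum of source activity densities on a common grid.

    Returns a DataFrame with columns ``theta_rad``, ``index`` and one
    column per source (the weighted component, for stacked-area plots);
    ``index`` equals the row-sum of the components exactly, and its
    trapezoidal integral over the circle is 1 because the weights sum to 1
    and each density integrates to 1.
    """
    grid = None
    parts = {}
    for source, w in weights.weights.items():
        if w == 0.0:
            continue
        if source not in densities:
            raise ConfigError(f"no fitted density for weighted source {source!r}")
        d = densities[source]
        if grid is None:
            grid = d.grid_
        elif d.grid_.shape != grid.shape or not np.allclose(d.grid_, grid):
            raise ConfigError("source densities are on different grids")
        parts[source] = w * d.density_
    out = pd.DataFrame({"theta_rad": grid})
    for source, comp in parts.items():
        out[source] = comp
    out["index"] = out[list(parts)].sum(axis=1)
    return out


def moving_window_overlap(deer_events: pd.DataFrame,
                          carnivore_events: pd.DataFrame,
                          start_date, end_date,
                          half_window_days: int = 5,
                          method: str = "auto",
                          min_n: int = 20,
                          **kde_kwargs) -> pd.DataFrame:
    """Daily moving-window overlap between deer and (pooled) carnivores.

    For each calendar day ``d`` from ``start_date`` to ``end_date``, events
    dated within ``d +/- half_window_days`` (inclusive, so an 11-day window
    by default) enter the two time-of-day samples and the overlap is
    estimated.  Windows where either sample falls below ``min_n`` yield a
    missing overlap, with the sample counts still reported.  Carnivore
    events are expected pre-pooled (one sample across species).

    Returns columns date, overlap, method, n_deer, n_carnivore.
    """
    days = pd.date_range(start_date, end_date, freq="D")
    if len(days) == 0:
        raise EmptySelectionError("empty moving-window date range")
    d_dates = pd.to_datetime(deer_events["timestamp"]).dt.normalize()
    c_dates = pd.to_datetime(carnivore_events["timestamp"]).dt.normalize()
    d_times = deer_events["time_of_day_rad"].to_numpy(dtype=float)
    c_times = carnivore_events["time_of_day_rad"].to_numpy(dtype=float)
    half = pd.Timedelta(days=half_window_days)

    rows = []
    for day in days:
        in_d = (d_dates >= day - half) & (d_dates <= day + half)
        in_c = (c_dates >= day - half) & (c_dates <= day + half)
        s1, s2 = d_times[in_d.to_numpy()], c_times[in_c.to_numpy()]
        n1, n2 = int(s1.size), int(s2.size)
        if min(n1, n2) < min_n:
            rows.append((day, np.nan, "", n1, n2))
            continue
        use = method
        if use == "auto":
            use = "delta4" if min(n1, n2) >= RELIABLE_N else "delta1"
        est = estimate_delta4 if use == "delta4" else estimate_delta1
        rows.append((day, est(s1, s2, **kde_kwargs), use, n1, n2))
    return pd.DataFrame(
        rows, columns=["date", "overlap", "method", "n_deer", "n_carnivore"]
    )


def round_percent(x: float) -> int:
    """Round to integer percent, halves away from zero (reporting style)."""
    return int(np.sign(x) * np.floor(np.abs(x) + 0.5))


def relative_overlap_change(delta_a: float, delta_b: float,
                            form: str = "reduction") -> float:
    """Signed percent change of overlap A relative to baseline B.

    ``form="reduction"`` gives ``100 * (B - A) / B`` (how much lower A is
    than the baseline); ``form="increase"`` gives ``100 * (A - B) / B``.
    """
    if delta_b <= 0:
        raise InvalidParameterError("baseline overlap must be positive")
    if form == "reduction":
        return 100.0 * (delta_b - delta_a) / delta_b
    if form == "increase":
        return 100.0 * (delta_a - delta_b) / delta_b
    raise InvalidParameterError(f"unknown form {form!r}")
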