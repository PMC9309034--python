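"""Cause-specific cumulative incidence under competing risks.

A cohort of radio-collared animals is monitored over a fixed study window
on a daily grid (day 0 = first monitoring day).  Each animal either
survives to the horizon, is right-censored on its last known day alive, or
dies of exactly one cause.  The Aalen-Johansen estimator generalizes
Kaplan-Meier to competing causes: with ``n(t)`` animals at risk on day
``t`` and ``d_k(t)`` deaths of cause ``k``,

    S(t)     = S(t-1) * (1 - sum_k d_k(t) / n(t)),
    CIF_k(t) = CIF_k(t-1) + S(t-1) * d_k(t) / n(t),

so that ``S(t) + sum_k CIF_k(t) = 1`` exactly whenever every death has a
typed cause.  Censorings tied with deaths on the same day are kept in the
risk set for that day's deaths (the usual events-before-censorings
convention).
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator

from .exceptions import DataError, EmptyCohortError

#: study clock of the motivating design: day 0 = July 15, day 77 = Sept 30.
DEFAULT_HORIZON = 77

CAUSES = (
    "vehicle",
    "coyote",
    "bear",
    "wolf",
    "bobcat",
    "unidentified_predation",
    "disease",
    "unknown",
)
NON_EVENT = ("survived", "censored")
OUTCOMES = NON_EVENT + CAUSES

STRATA = ("fawn", "adult_female", "adult_male")

__all__ = [
    "AalenJohansenEstimator",
    "aalen_johansen",
    "mortality_summary",
    "validate_histories",
    "CAUSES",
    "OUTCOMES",
    "STRATA",
    "DEFAULT_HORIZON",
]


def validate_histories(histories: pd.DataFrame, horizon: int) -> pd.DataFrame:
    """Check a subject-history table against its schema.

    Required columns: animal_id, stratum, start_day, end_day, outcome.
    """
    required = {"animal_id", "stratum", "start_day", "end_day", "outcome"}
    missing = required - set(histories.columns)
    if missing:
        raise DataError(f"history table missing columns: {sorted(missing)}")
    bad = set(histories["outcome"]) - set(OUTCOMES)
    if bad:
        raise DataError(f"unknown outcome labels: {sorted(bad)}")
    start = histories["start_day"].to_numpy()
    end = histories["end_day"].to_numpy()
    if (start < 0).any() or (end > horizon).any() or (start > end).any():
        raise DataError(
            f"day columns must satisfy 0 <= start_day <= end_day <= {horizon}"
        )
    return histories


class AalenJohansenEstimator(BaseEstimator):
    """Aalen-Johansen cumulative incidence on a daily grid.

    Parameters
    ----------
    horizon : int, default=77
        Last study day; the estimate is tabulated on days ``0..horizon``.
    causes : sequence of str, optional
        Closed vocabulary of death causes; defaults to the package-wide
        cause list.

    Attributes
    ----------
    days_ : ndarray, shape (horizon + 1,)
    survival_ : ndarray
        Overall survival ``S(t)`` per day.
    cif_ : dict of str -> ndarray
        Cause-specific cumulative incidence per day, for every cause in the
        vocabulary (identically zero for unobserved causes).
    n_at_risk_ : ndarray
        Number of animals at risk of a day-``t`` event.
    n_subjects_ : int
    """

    def __init__(self, horizon: int = DEFAULT_HORIZON, causes=CAUSES):
        self.horizon = horizon
        self.causes = causes

    def fit(self, histories: pd.DataFrame, y=None) -> "AalenJohansenEstimator":
        histories = validate_histories(histories, self.horizon)
        if len(histories) == 0:
            raise EmptyCohortError("no subjects in cohort")
        start = histories["start_day"].to_numpy(dtype=int)
        end = histories["end_day"].to_numpy(dtype=int)
        outcome = histories["outcome"].to_numpy()

        T = self.horizon
        days = np.arange(T + 1)
        # at risk for the day-t transition: under observation during (t-1, t];
        # a subject whose whole record is the single day t still counts.
        at_risk = np.zeros(T + 1, dtype=int)
        deaths = {k: np.zeros(T + 1, dtype=int) for k in self.causes}
        for s, e, o in zip(start, end, outcome):
            lo = s + 1 if e > s else max(e, 1)
            at_risk[lo : max(e, lo) + 1] += 1
            if o not in NON_EVENT:
                deaths[o][max(e, lo)] += 1

        surv = np.ones(T + 1)
        cif = {k: np.zeros(T + 1) for k in self.causes}
        for t in range(1, T + 1):
            n_t = at_risk[t]
            d_tot = sum(deaths[k][t] for k in self.causes)
            for k in self.causes:
                cif[k][t] = cif[k][t - 1]
                if deaths[k][t]:
                    cif[k][t] += surv[t - 1] * deaths[k][t] / n_t
            surv[t] = surv[t - 1] * (1.0 - (d_tot / n_t if n_t else 0.0))

        self.days_ = days
        self.survival_ = surv
        self.cif_ = cif
        self.n_at_risk_ = at_risk
        self.n_subjects_ = int(len(histories))
        return self

    def to_frame(self, stratum: str | None = None) -> pd.DataFrame:
        """Long-format table: stratum, day, measure, cause, value."""
        rows = [
            pd.DataFrame(
                {"stratum": stratum, "day": self.days_, "measure": "survival",
                 "cause": "", "value": self.survival_}
            )
        ]
        for k in self.causes:
            rows.append(
                pd.DataFrame(
                    {"stratum": stratum, "day": self.days_, "measure": "cif",
                     "cause": k, "value": self.cif_[k]}
                )
            )
        return pd.concat(rows, ignore_index=True)

    def terminal_cif(self) -> dict[str, float]:
        return {k: float(v[-1]) for k, v in self.cif_.items()}


def aalen_johansen(histories: pd.DataFrame, stratum: str | None = None,
                   horizon: int = DEFAULT_HORIZON) -> AalenJohansenEstimator:
    """Fit the estimator, optionally restricted to one stratum."""
    if stratum is not None:
        histories = histories[histories["stratum"] == stratum]
        if len(histories) == 0:
            raise EmptyCohortError(f"no subjects in stratum {stratum!r}")
    return AalenJohansenEstimator(horizon=horizon).fit(histories)


def mortality_summary(est: AalenJohansenEstimator) -> dict:
    """Terminal cumulative incidence per cause plus the total mortality."""
    terminal = est.terminal_cif()
    return {"by_cause": terminal, "total": float(sum(terminal.values()))}
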