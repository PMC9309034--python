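"""Synthetic detection and mortality generators: determinism and recovery."""

import numpy as np
import pandas as pd
import pytest

from dielrisk.competing_risks import aalen_johansen, validate_histories
from dielrisk.detections import validate_images
from dielrisk.exceptions import InvalidParameterError
from dielrisk.kde import TWO_PI
from dielrisk.overlap import estimate_delta4
from dielrisk.synthetic import (
    ActivityMixtureSpec,
    CohortSpec,
    analytic_cif,
    events_to_images,
    gen_detection_times,
    gen_mortality_cohort,
    hazards_from_terminal_cif,
    mixture_pdf,
    study_scenario,
    true_overlap,
)

from oracles import true_overlap_grid

pytestmark = pytest.mark.filterwarnings("ignore:sample size")

CREPUSCULAR = ActivityMixtureSpec(
    ((np.pi / 2, 8.0, 0.5), (5 * np.pi / 3, 8.0, 0.5)), "crepuscular"
)


class TestSpecs:
    def test_invalid_mixture_rejected_with_reason(self):
        with pytest.raises(InvalidParameterError, match="sum"):
            ActivityMixtureSpec(((0.0, 1.0, 0.4), (1.0, 1.0, 0.4)), "bad")
        with pytest.raises(InvalidParameterError, match="kappa"):
            ActivityMixtureSpec(((0.0, -1.0, 1.0),), "bad")

    def test_invalid_cohort_rejected(self):
        with pytest.raises(InvalidParameterError):
            CohortSpec(n=10, daily_hazards={"coyote": 1.2})
        with pytest.raises(InvalidParameterError):
            CohortSpec(n=10, daily_hazards={"coyote": 0.6},
                       daily_censor_prob=0.5)


class TestDetectionGenerator:
    def test_same_seed_identical_dataset(self):
        a = gen_detection_times(CREPUSCULAR, 200, ("2018-07-15", "2018-09-15"), 9)
        b = gen_detection_times(CREPUSCULAR, 200, ("2018-07-15", "2018-09-15"), 9)
        pd.testing.assert_frame_equal(a, b)

    def test_output_passes_detection_module_preconditions(self):
        events = gen_detection_times(
            CREPUSCULAR, 50, ("2018-07-15", "2018-09-15"), 1,
            species="deer", group="nursery_group",
        )
        validate_images(events_to_images(events))
        assert ((0 <= events["time_of_day_rad"])
                & (events["time_of_day_rad"] < TWO_PI)).all()

    def test_crepuscular_sample_consistent_with_its_own_density(self):
        s1 = gen_detection_times(CREPUSCULAR, 5000, ("2018-07-15", "2018-09-15"),
                                 1)["time_of_day_rad"]
        s2 = gen_detection_times(CREPUSCULAR, 5000, ("2018-07-15", "2018-09-15"),
                                 2)["time_of_day_rad"]
        assert estimate_delta4(s1, s2) > 0.9

    def test_high_concentration_limit_has_tiny_circular_variance(self):
        spec = ActivityMixtureSpec(((1.0, 500.0, 1.0),), "spike")
        t = gen_detection_times(spec, 2000, ("2018-07-15", "2018-07-16"),
                                3)["time_of_day_rad"].to_numpy()
        rbar = np.hypot(np.cos(t).sum(), np.sin(t).sum()) / t.size
        assert 1.0 - rbar < 0.01  # circular variance


class TestCohortGenerator:
    def test_same_seed_identical_cohort(self):
        spec = CohortSpec(n=100, daily_hazards={"coyote": 0.002})
        pd.testing.assert_frame_equal(
            gen_mortality_cohort(spec, 5), gen_mortality_cohort(spec, 5)
        )

    def test_zero_hazards_everyone_survives(self):
        spec = CohortSpec(n=50, daily_hazards={"coyote": 0.0})
        cohort = gen_mortality_cohort(spec, 1)
        assert (cohort["outcome"] == "survived").all()
        assert (cohort["end_day"] == 78).all()

    def test_single_cause_matches_closed_form(self):
        spec = CohortSpec(n=10_000, daily_hazards={"coyote": 0.01},
                          horizon_days=78)
        cohort = gen_mortality_cohort(spec, 7)
        empirical = (cohort["outcome"] == "coyote").mean()
        assert empirical == pytest.approx(1.0 - 0.99**78, abs=0.01)

    def test_proportional_hazards_split_events_two_to_one(self):
        spec = CohortSpec(n=20_000, daily_hazards={"a_cause": 0.004,
                                                   "b_cause": 0.002})
        # cause labels outside the standard vocabulary are fine here: the
        # generator itself has no vocabulary, only the survival schema does
        cohort = gen_mortality_cohort(spec, 11)
        na = (cohort["outcome"] == "a_cause").sum()
        nb = (cohort["outcome"] == "b_cause").sum()
        assert na / nb == pytest.approx(2.0, rel=0.1)

    def test_output_passes_survival_module_schema(self):
        spec = CohortSpec(n=30, daily_hazards={"coyote": 0.002},
                          daily_censor_prob=0.001)
        validate_histories(gen_mortality_cohort(spec, 2), horizon=78)


class TestAnalyticTruth:
    def test_analytic_cif_sums_to_total_mortality(self):
        hz = {"a": 0.001, "b": 0.003}
        cif = analytic_cif(hz, 78)
        total = 1.0 - (1.0 - sum(hz.values())) ** 78
        assert sum(cif.values()) == pytest.approx(total, abs=1e-12)

    def test_hazard_calibration_roundtrip(self):
        terminal = {"coyote": 0.04, "bear": 0.01, "vehicle": 0.03}
        hz = hazards_from_terminal_cif(terminal, 78)
        back = analytic_cif(hz, 78)
        for k in terminal:
            assert back[k] == pytest.approx(terminal[k], rel=1e-9)

    def test_quadrature_overlap_agrees_with_independent_grid_oracle(self):
        a = ActivityMixtureSpec(((0.0, 2.0, 0.6), (2.0, 4.0, 0.4)), "a")
        b = ActivityMixtureSpec(((np.pi, 1.5, 1.0),), "b")
        assert true_overlap(a, b) == pytest.approx(
            true_overlap_grid(a.components, b.components), abs=1e-6
        )

    def test_mixture_pdf_normalizes(self):
        grid = np.linspace(0, TWO_PI, 20001)
        assert np.trapezoid(mixture_pdf(CREPUSCULAR, grid), grid) == pytest.approx(
            1.0, abs=1e-9
        )


class TestScenarioBundle:
    def test_same_seed_identical_bundle(self):
        a = study_scenario(seed=4, scale=0.02)
        b = study_scenario(seed=4, scale=0.02)
        pd.testing.assert_frame_equal(a.detections, b.detections)
        pd.testing.assert_frame_equal(a.mortality, b.mortality)
        assert a.truth == b.truth

    def test_bundle_shapes_and_truth_sidecar(self):
        bundle = study_scenario(seed=4, scale=0.02)
        assert set(bundle.truth) >= {"mixtures", "cohorts",
                                     "analytic_terminal_cif", "horizon_days"}
        counts = bundle.detections.groupby("species").size()
        assert counts["human"] > counts["wolf"]  # field-scale ordering
        strata = set(bundle.mortality["stratum"])
        assert strata == {"fawn", "adult_female", "adult_male"}

    def test_fawn_mortality_recovered_from_bundle(self):
        bundle = study_scenario(seed=4, scale=0.02)
        truth_total = sum(bundle.truth["analytic_terminal_cif"]["fawn"].values())
        fit = aalen_johansen(bundle.mortality, stratum="fawn",
                             horizon=bundle.truth["horizon_days"])
        est = sum(fit.terminal_cif().values())
        assert truth_total == pytest.approx(0.16, abs=1e-9)
        assert est == pytest.approx(truth_total, abs=0.04)
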