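"""Risk weights, combined diel risk index, moving-window overlap."""

import numpy as np
import pandas as pd
import pytest

from dielrisk.exceptions import ConfigError, InvalidParameterError, UndefinedWeightsError
from dielrisk.kde import TWO_PI, fit_circular_kde
from dielrisk.risk import (
    compute_risk_index,
    compute_risk_weights,
    moving_window_overlap,
    relative_overlap_change,
    round_percent,
)
from dielrisk.synthetic import ActivityMixtureSpec, gen_detection_times

pytestmark = pytest.mark.filterwarnings("ignore:sample size")


class TestWeights:
    def test_renormalizes_over_identified_causes(self):
        rw = compute_risk_weights(
            {"coyote": 0.04, "wolf": 0.04, "unidentified_predation": 0.02}
        )
        assert rw.weights["coyote"] == pytest.approx(0.5)
        assert rw.weights["wolf"] == pytest.approx(0.5)
        assert rw.excluded_mass == pytest.approx(0.02)
        assert sum(rw.weights.values()) == pytest.approx(1.0, abs=1e-9)

    def test_single_cause_gets_weight_one(self):
        rw = compute_risk_weights({"bear": 0.013})
        assert rw.weights["black_bear"] == 1.0

    def test_forty_percent_of_known_mortality_weighs_point_four(self):
        rw = compute_risk_weights(
            {"coyote": 0.40, "wolf": 0.35, "vehicle": 0.25}
        )
        assert rw.weights["coyote"] == pytest.approx(0.4)

    def test_scale_free(self):
        cifs = {"coyote": 0.04, "bear": 0.01, "vehicle": 0.03}
        a = compute_risk_weights(cifs)
        b = compute_risk_weights({k: 7.7 * v for k, v in cifs.items()})
        for k in a.weights:
            assert a.weights[k] == pytest.approx(b.weights[k], abs=1e-12)

    def test_vehicle_mortality_maps_to_human_activity(self):
        rw = compute_risk_weights({"vehicle": 0.02, "wolf": 0.02})
        assert rw.weights["human"] == pytest.approx(0.5)
        assert rw.weights["wolf"] == pytest.approx(0.5)
        # causes absent from the table carry zero weight, not an error
        assert rw.weights["coyote"] == 0.0

    def test_all_zero_identified_cifs_rejected(self):
        with pytest.raises(UndefinedWeightsError):
            compute_risk_weights({"disease": 0.05, "coyote": 0.0})


class TestRiskIndex:
    def _densities(self, rng, specs):
        out = {}
        for i, (name, mu, kappa) in enumerate(specs):
            sample = rng.vonmises(mu, kappa, 400) % TWO_PI
            out[name] = fit_circular_kde(sample)
        return out

    def test_uniform_sources_give_flat_index(self, rng):
        dens = {
            name: fit_circular_kde(rng.uniform(0, TWO_PI, 5000))
            for name in ("coyote", "human")
        }
        rw = compute_risk_weights({"coyote": 0.5, "vehicle": 0.5})
        idx = compute_risk_index(dens, rw)
        np.testing.assert_allclose(idx["index"], 1.0 / TWO_PI, atol=0.01)

    def test_weight_one_source_reproduces_its_density(self, rng):
        dens = self._densities(rng, [("wolf", 0.0, 2.0)])
        rw = compute_risk_weights({"wolf": 0.04})
        idx = compute_risk_index(dens, rw)
        np.testing.assert_array_equal(idx["index"], dens["wolf"].density_)

    def test_half_half_weights_average_the_densities(self, rng):
        dens = self._densities(rng, [("wolf", 0.0, 2.0), ("human", np.pi, 3.0)])
        rw = compute_risk_weights({"wolf": 0.02, "vehicle": 0.02})
        idx = compute_risk_index(dens, rw)
        expected = 0.5 * (dens["wolf"].density_ + dens["human"].density_)
        np.testing.assert_allclose(idx["index"], expected, atol=1e-12)
        # decomposition: index is the exact sum of per-source columns
        np.testing.assert_array_equal(
            idx["index"], idx[["wolf", "human"]].sum(axis=1)
        )

    def test_index_integrates_to_one(self, rng):
        dens = self._densities(
            rng, [("wolf", 0.0, 2.0), ("coyote", 1.0, 1.5), ("human", np.pi, 3.0)]
        )
        rw = compute_risk_weights({"wolf": 0.01, "coyote": 0.04, "vehicle": 0.03})
        idx = compute_risk_index(dens, rw)
        grid = np.append(idx["theta_rad"].to_numpy(), TWO_PI)
        vals = np.append(idx["index"].to_numpy(), idx["index"].iloc[0])
        assert np.trapezoid(vals, grid) == pytest.approx(1.0, abs=1e-6)

    def test_missing_density_for_weighted_source_is_config_error(self, rng):
        dens = self._densities(rng, [("wolf", 0.0, 2.0)])
        rw = compute_risk_weights({"wolf": 0.02, "coyote": 0.02})
        with pytest.raises(ConfigError, match="coyote"):
            compute_risk_index(dens, rw)


def _dated_events(rng, spec, n_per_day, dates, species="deer", group="nursery_group"):
    frames = [
        gen_detection_times(spec, n_per_day, (d, d), seed=seed, species=species,
                            group=group)
        for seed, d in enumerate(dates, start=100 + rng.integers(1000))
    ]
    return pd.concat(frames, ignore_index=True)


class TestMovingWindow:
    def test_identical_distributions_give_high_overlap(self, rng):
        spec = ActivityMixtureSpec(((1.0, 2.0, 1.0),), "flatish")
        dates = pd.date_range("2018-07-15", "2018-08-05").strftime("%Y-%m-%d")
        deer = _dated_events(rng, spec, 50, dates)
        carn = _dated_events(rng, spec, 50, dates, species="coyote", group="not_deer")
        series = moving_window_overlap(deer, carn, "2018-07-20", "2018-08-01")
        assert series["overlap"].notna().all()
        assert (series["overlap"] > 0.8).all()

    def test_window_boundary_inclusive_at_five_days(self, rng):
        spec = ActivityMixtureSpec(((1.0, 2.0, 1.0),), "s")
        # deer every day; carnivores only 5 days before the target day
        deer = _dated_events(
            rng, spec, 30, pd.date_range("2018-07-15", "2018-07-25").strftime("%Y-%m-%d")
        )
        carn = _dated_events(rng, spec, 30, ["2018-07-15"], species="wolf",
                             group="not_deer")
        series = moving_window_overlap(deer, carn, "2018-07-20", "2018-07-21",
                                       min_n=20)
        # Jul 20 window reaches back to Jul 15 (inclusive): estimable
        assert np.isfinite(series["overlap"].iloc[0])
        # Jul 21 window starts Jul 16: the Jul 15 carnivores fall out
        assert np.isnan(series["overlap"].iloc[1])
        assert series["n_carnivore"].iloc[1] == 0

    def test_small_windows_reported_missing_with_counts(self, rng):
        spec = ActivityMixtureSpec(((1.0, 2.0, 1.0),), "s")
        deer = _dated_events(rng, spec, 30, ["2018-07-20"])
        carn = _dated_events(rng, spec, 3, ["2018-07-20"], species="coyote",
                             group="not_deer")
        series = moving_window_overlap(deer, carn, "2018-07-20", "2018-07-20",
                                       min_n=20)
        assert np.isnan(series["overlap"].iloc[0])
        assert series["n_deer"].iloc[0] == 30
        assert series["n_carnivore"].iloc[0] == 3


class TestRelativeChange:
    @pytest.mark.parametrize(
        "a, b, form, expected_pct",
        [
            (0.61, 0.86, "reduction", 29),   # nursery vs adult, wolf
            (0.65, 0.85, "reduction", 24),   # black bear
            (0.71, 0.51, "increase", 39),    # human
            (0.5, 0.5, "reduction", 0),
        ],
    )
    def test_reported_percentages(self, a, b, form, expected_pct):
        assert round_percent(relative_overlap_change(a, b, form=form)) == expected_pct

    def test_zero_baseline_rejected(self):
        with pytest.raises(InvalidParameterError):
            relative_overlap_change(0.5, 0.0)

    def test_rounding_half_away_from_zero(self):
        assert round_percent(0.5) == 1
        assert round_percent(-0.5) == -1
        assert round_percent(23.49) == 23
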