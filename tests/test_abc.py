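import datetime as dt

import numpy as np
import pytest

from serialabc import (
    GenerationClock,
    MutationModel,
    SamplingDesign,
    compare_generation_clocks,
    parameter_posterior,
    retain_nearest,
    scenario_posteriors,
    sensitivity_drop_stats,
    simulate_reference_table,
)
from serialabc.abc import ReferenceTable
from serialabc.scenarios import build_scenario
from serialabc.sumstats import stat_layout


SMALL_DESIGN = SamplingDesign(
    sample_dates=[dt.date(2009, 3, 25), dt.date(2009, 9, 1), dt.date(2010, 4, 13)],
    sample_sizes=[12, 12, 12],
    n_loci=4,
    spray_dates=[dt.date(2008, 10, 1), dt.date(2009, 6, 14), dt.date(2009, 12, 18)],
)
SMALL_CLOCK = GenerationClock(18.0, dt.date(2010, 4, 13))


@pytest.fixture(scope="module")
def small_table():
    specs = [build_scenario(s, SMALL_DESIGN, SMALL_CLOCK) for s in (1, 2)]
    return simulate_reference_table(specs, 500, SMALL_DESIGN, SMALL_CLOCK, seed=17)


class TestReferenceTable:
    def test_row_count_and_labels(self, small_table):
        assert small_table.n_rows == 1000
        assert sorted(set(small_table.scenario_ids)) == [1, 2]
        assert np.isfinite(small_table.stats).all()

    def test_fixed_seed_reproducible(self):
        specs = [build_scenario(1, SMALL_DESIGN, SMALL_CLOCK)]
        t1 = simulate_reference_table(specs, 100, SMALL_DESIGN, SMALL_CLOCK, seed=3)
        t2 = simulate_reference_table(specs, 100, SMALL_DESIGN, SMALL_CLOCK, seed=3)
        np.testing.assert_array_equal(t1.stats, t2.stats)
        np.testing.assert_array_equal(t1.params, t2.params)

    def test_robust_scale_matches_direct_recomputation(self, small_table):
        scale = small_table.robust_scale()
        med = np.median(small_table.stats, axis=0)
        direct = 1.4826 * np.median(np.abs(small_table.stats - med), axis=0)
        np.testing.assert_allclose(scale, direct, atol=1e-12)

    def test_csv_roundtrip(self, small_table, tmp_path):
        path = tmp_path / "table.csv"
        small_table.to_csv(path)
        back = ReferenceTable.from_csv(path)
        np.testing.assert_allclose(back.stats, small_table.stats)
        assert back.param_names == small_table.param_names

    def test_too_few_simulations_rejected(self):
        specs = [build_scenario(1, SMALL_DESIGN, SMALL_CLOCK)]
        with pytest.raises(ValueError, match=">= 100"):
            simulate_reference_table(specs, 50, SMALL_DESIGN, SMALL_CLOCK, seed=1)


class TestRetention:
    def test_observed_equal_to_row_gives_distance_zero(self, small_table):
        obs = small_table.stats[123].copy()
        ret = retain_nearest(small_table, obs, fraction=0.05)
        assert ret.indices[0] == 123
        assert ret.distances[0] == 0.0

    def test_retained_count_is_ceil_fraction(self, small_table):
        ret = retain_nearest(small_table, small_table.stats[0], fraction=0.01)
        assert ret.n_retained == 10
        assert (np.diff(ret.distances) >= 0).all()

    def test_rescaling_a_column_leaves_retained_set_unchanged(self, small_table):
        obs = small_table.stats[7].copy()
        ret1 = retain_nearest(small_table, obs, fraction=0.02)
        scaled = ReferenceTable(
            scenario_ids=small_table.scenario_ids,
            params=small_table.params,
            stats=small_table.stats * np.where(np.arange(small_table.stats.shape[1]) == 3, 7.0, 1.0),
            stat_names=small_table.stat_names,
            param_names=small_table.param_names,
            n_groups=small_table.n_groups,
        )
        obs2 = obs * np.where(np.arange(obs.size) == 3, 7.0, 1.0)
        ret2 = retain_nearest(scaled, obs2, fraction=0.02)
        np.testing.assert_array_equal(ret1.indices, ret2.indices)

    def test_invalid_inputs_rejected(self, small_table):
        with pytest.raises(ValueError):
            retain_nearest(small_table, small_table.stats[0], fraction=0.0)
        with pytest.raises(ValueError):
            retain_nearest(small_table, small_table.stats[0][:-1])


class TestScenarioPosteriors:
    def test_single_scenario_degenerate(self, small_table):
        obs = small_table.stats[small_table.scenario_ids == 2][0]
        ret = retain_nearest(small_table, obs, fraction=0.01)
        ret.scenario_ids = np.full_like(ret.scenario_ids, 2)
        sp = scenario_posteriors(ret)
        assert sp["logistic"] == {2: 1.0}
        assert sp["method"] == "degenerate"

    def test_counts_equal_retained_proportions(self, small_table):
        ret = retain_nearest(small_table, small_table.stats[0], fraction=0.05)
        sp = scenario_posteriors(ret)
        for s in (1, 2):
            assert sp["counts"].get(s, 0.0) == pytest.approx(
                (ret.scenario_ids == s).mean()
            )
        assert sum(sp["logistic"].values()) == pytest.approx(1.0, abs=1e-9)

    def test_identical_specs_give_symmetric_posteriors(self):
        # two "scenarios" with identical generating processes: posterior
        # must be 0.5/0.5 up to Monte-Carlo error of the counting estimator
        spec = build_scenario(1, SMALL_DESIGN, SMALL_CLOCK)
        table = simulate_reference_table(
            [spec, spec], 400, SMALL_DESIGN, SMALL_CLOCK, seed=23, labels=[0, 1]
        )
        rng = np.random.default_rng(2)
        obs = table.stats[rng.integers(table.n_rows)]
        ret = retain_nearest(table, obs, fraction=0.25)
        sp = scenario_posteriors(ret)
        m = ret.n_retained
        se = np.sqrt(0.25 / m)
        assert abs(sp["counts"][0] - 0.5) < 3 * se
        assert abs(sp["logistic"][0] - 0.5) < 4 * se

    def test_counting_se_does_not_increase_with_more_simulations(self, small_table):
        # SE of the counting estimator shrinks as the retained set grows
        obs = small_table.stats[5]
        ses = []
        for frac in (0.01, 0.1):
            ret = retain_nearest(small_table, obs, fraction=frac)
            p = (ret.scenario_ids == 2).mean()
            ses.append(np.sqrt(max(p * (1 - p), 0.25 / ret.n_retained) / ret.n_retained))
        assert ses[1] <= ses[0]


class TestParameterPosterior:
    def test_constant_values_give_point_interval(self):
        out = parameter_posterior(np.full(100, 321.0))
        assert out["median"] == 321.0
        assert out["ci95_quantile"] == [321.0, 321.0]
        assert out["ci95_density"] == [321.0, 321.0]

    def test_uniform_sample_quantiles(self):
        rng = np.random.default_rng(5)
        vals = rng.uniform(0, 1, size=10000)
        out = parameter_posterior(vals)
        assert out["median"] == pytest.approx(0.5, abs=0.015)
        assert out["ci95_quantile"][0] == pytest.approx(0.025, abs=0.01)
        assert out["ci95_quantile"][1] == pytest.approx(0.975, abs=0.01)
        lo, hi = out["ci95_density"]
        assert lo <= out["median"] <= hi

    def test_interval_contains_median(self):
        rng = np.random.default_rng(6)
        vals = np.exp(rng.normal(5, 1, size=500))
        out = parameter_posterior(vals)
        assert out["ci95_quantile"][0] <= out["median"] <= out["ci95_quantile"][1]
        assert out["ci95_density"][0] <= out["median"] <= out["ci95_density"][1]

    def test_too_few_draws_rejected(self):
        with pytest.raises(ValueError, match="50"):
            parameter_posterior(np.ones(10))

    def test_regression_adjustment_runs_on_log_scale(self):
        rng = np.random.default_rng(7)
        n = 400
        resid = rng.normal(0, 1, size=(n, 3))
        vals = np.exp(6 + resid @ np.array([0.5, -0.2, 0.1]) + rng.normal(0, 0.1, n))
        d = np.linspace(0.1, 1.0, n)
        out = parameter_posterior(vals, residuals=resid, distances=d, regression_adjust=True)
        raw = parameter_posterior(vals)
        # removing the regression signal tightens the interval
        w_adj = out["ci95_quantile"][1] - out["ci95_quantile"][0]
        w_raw = raw["ci95_quantile"][1] - raw["ci95_quantile"][0]
        assert w_adj < w_raw


class TestSensitivity:
    def test_baseline_row_matches_direct_call(self, small_table):
        obs = small_table.stats[11]
        df = sensitivity_drop_stats(small_table, obs, (1, 2), fraction=0.02)
        ret = retain_nearest(small_table, obs, fraction=0.02)
        sp = scenario_posteriors(ret)
        base = df[df.removed == "full"].iloc[0]
        assert base["p2_logistic"] == pytest.approx(sp["logistic"].get(2, 0.0))
        assert base["p2_counts"] == pytest.approx(sp["counts"].get(2, 0.0))

    def test_one_row_per_category_plus_baseline(self, small_table):
        df = sensitivity_drop_stats(small_table, small_table.stats[0], (1, 2))
        _, cats = stat_layout(small_table.n_groups)
        assert len(df) == len(cats) + 1
        assert set(df.removed) == {"full"} | {f"drop:{c}" for c in cats}


class TestClockComparison:
    def test_single_clock_degenerate(self, small_table):
        obs = small_table.stats[0]
        out = compare_generation_clocks(
            obs, 1, SMALL_DESIGN, [SMALL_CLOCK], n_per_clock=100, seed=1
        )
        assert out["logistic"] == {18.0: 1.0}

    def test_identical_clocks_symmetric(self):
        spec_obs = build_scenario(1, SMALL_DESIGN, SMALL_CLOCK)
        table = simulate_reference_table([spec_obs], 200, SMALL_DESIGN, SMALL_CLOCK, seed=9)
        obs = table.stats[0]
        clocks = [GenerationClock(18.0, SMALL_CLOCK.reference_date)] * 2
        out = compare_generation_clocks(
            obs, 1, SMALL_DESIGN, clocks, n_per_clock=400, seed=31, fraction=0.25
        )
        probs = list(out["counts"].values())
        assert len(probs) == 2 and sum(probs) == pytest.approx(1.0)
        m = 200  # retained rows
        assert abs(probs[0] - 0.5) < 3 * np.sqrt(0.25 / m)
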