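"""Analysis layer: engagement summaries, branching detection, regime
classification, the annealing optimiser, relative efficiency and sweeps."""

import numpy as np
import pytest

from polyethism import (
    AGE_POLYETHISM,
    BRANCHING_MIXED,
    REGULATION_FAILURE,
    EnvironmentParams,
    RegimeThresholds,
    SAParams,
    Trajectory,
    classify_regime,
    detect_branching,
    optimal_allocation,
    parameter_sweep,
    permutation_pvalue,
    polyethism_index,
    relative_efficiency,
    sign_flip_pvalue,
    tail_engagement,
)
from polyethism.analysis import (
    achieved_mean_payoff,
    aggregate_regimes,
    engagement_summary,
    mean_payoff,
)

from conftest import make_config


def synthetic_traj(x_rows, ages, payoff_rows=None, p_rows=None):
    x_rows = np.asarray(x_rows, dtype=float)
    if payoff_rows is None:
        payoff_rows = np.zeros((x_rows.shape[0] - 1, x_rows.shape[1]))
    return Trajectory(model="srt" if p_rows is not None else "sl",
                      x=x_rows, ages=np.asarray(ages), payoffs=payoff_rows,
                      p=None if p_rows is None else np.asarray(p_rows, float))


class TestEngagementSummaries:
    def test_constant_trajectory_summary_is_the_constant(self):
        rows = np.full((11, 4), 0.3)
        traj = synthetic_traj(rows, [0, 0, 1, 1])
        vals = tail_engagement(traj, 0.5)
        np.testing.assert_allclose(vals, 0.3)
        s = engagement_summary(traj, 0.5)
        assert s["young_mean"] == pytest.approx(0.3)
        assert s["old_mean"] == pytest.approx(0.3)

    def test_half_and_half_population_mean(self):
        rows = np.tile([0.0, 1.0, 0.0, 1.0], (6, 1))
        traj = synthetic_traj(rows, [0, 0, 1, 1])
        s = engagement_summary(traj, 0.5)
        assert s["young_mean"] == pytest.approx(0.5)

    def test_linear_ramp_tail_mean_is_closed_form(self):
        steps = np.linspace(0.0, 1.0, 101)[:, None]          # ramp 0..1 over 101 rows
        traj = synthetic_traj(np.repeat(steps, 4, axis=1), [0, 0, 1, 1])
        vals = tail_engagement(traj, 0.2)                     # last 20 rows: 81..100
        expected = np.mean(np.linspace(0.0, 1.0, 101)[-20:])
        np.testing.assert_allclose(vals, expected)

    def test_engagement_uses_p_for_stimulus_model(self):
        x_rows = np.full((3, 2), 0.9)
        p_rows = np.full((3, 2), 0.1)
        traj = synthetic_traj(x_rows, [0, 1], p_rows=p_rows)
        np.testing.assert_allclose(tail_engagement(traj, 1.0), 0.1)


class TestBranchingDetection:
    def test_single_cluster_not_branched(self):
        branched, lo, hi = detect_branching(np.full(50, 0.95))
        assert not branched

    def test_even_split_branched(self):
        vals = np.r_[np.full(25, 0.05), np.full(25, 0.95)]
        branched, lo, hi = detect_branching(vals)
        assert branched
        assert lo.size == 25 and hi.size == 25

    def test_minority_below_min_frac_not_branched(self):
        vals = np.r_[np.full(95, 0.05), np.full(5, 0.95)]
        branched, _, _ = detect_branching(vals, min_frac=0.1)
        assert not branched

    def test_threshold_validation(self):
        with pytest.raises(ValueError):
            detect_branching([0.5], lo=0.9, hi=0.1)


class TestPolyethismIndexAndRegime:
    def test_identical_ages_zero_index(self):
        rows = np.tile(np.linspace(0, 1, 8), (5, 1))
        traj = synthetic_traj(rows, [0, 1] * 4)
        # same distribution per age: alternating identical pairs
        assert polyethism_index(traj, 1.0) == pytest.approx(
            abs(rows[0][::2].mean() - rows[0][1::2].mean()))

    def test_perfect_separation_is_one(self):
        rows = np.tile(np.r_[np.ones(4), np.zeros(4)], (5, 1))
        traj = synthetic_traj(rows, [0] * 4 + [1] * 4)
        assert polyethism_index(traj, 0.5) == pytest.approx(1.0)

    def test_hand_computed_gap(self):
        rows = np.tile(np.r_[np.full(2, 0.9), np.full(2, 0.25)], (5, 1))
        traj = synthetic_traj(rows, [0, 0, 1, 1])
        assert polyethism_index(traj, 0.5) == pytest.approx(0.65)

    def test_missing_age_class_rejected(self):
        traj = synthetic_traj(np.full((3, 4), 0.5), [0, 0, 0, 0])
        with pytest.raises(ValueError):
            polyethism_index(traj)

    @pytest.mark.parametrize("values, ages, expected", [
        (np.full(20, 0.97), [0, 1] * 10, REGULATION_FAILURE),
        (np.full(20, 0.03), [0, 1] * 10, REGULATION_FAILURE),
        (np.r_[np.zeros(10), np.ones(10)], [1] * 10 + [0] * 10, AGE_POLYETHISM),
        (np.r_[np.zeros(10), np.ones(10)], [0, 1] * 10, BRANCHING_MIXED),
        (np.full(20, 0.5), [0, 1] * 10, BRANCHING_MIXED),   # interior, unbranched
    ])
    def test_classification_taxonomy(self, values, ages, expected):
        assert classify_regime(values, ages) == expected

    def test_classification_permutation_invariant_within_age(self):
        rng = np.random.default_rng(0)
        values = np.r_[rng.uniform(0, 0.1, 10), rng.uniform(0.9, 1.0, 10)]
        ages = np.r_[np.ones(10, int), np.zeros(10, int)]
        base = classify_regime(values, ages)
        for _ in range(10):
            perm_young = rng.permutation(np.flatnonzero(ages == 0))
            perm_old = rng.permutation(np.flatnonzero(ages == 1))
            v2 = values.copy()
            v2[ages == 0] = values[perm_young]
            v2[ages == 1] = values[perm_old]
            assert classify_regime(v2, ages) == base

    def test_purity_threshold_separates_mixed_from_polyethism(self):
        values = np.r_[np.zeros(10), np.ones(10)]
        ages = np.r_[np.ones(9, int), 0, 1, np.zeros(9, int)]  # one defector per branch
        th = RegimeThresholds(purity=0.95)
        assert classify_regime(values, ages, th) == BRANCHING_MIXED
        th2 = RegimeThresholds(purity=0.9)
        assert classify_regime(values, ages, th2) == AGE_POLYETHISM


class TestPermutationMachinery:
    def test_individual_permutation_uniform_under_null(self):
        rng = np.random.default_rng(5)
        ps = []
        for _ in range(40):
            vals = rng.random(40)
            ages = np.r_[np.zeros(20, int), np.ones(20, int)]
            ps.append(permutation_pvalue(vals, ages, 200, rng))
        # under the null p-values should not pile up near 0
        assert np.mean(np.asarray(ps) < 0.05) < 0.25

    def test_sign_flip_detects_consistent_direction(self):
        assert sign_flip_pvalue([0.9] * 10) < 0.01

    def test_sign_flip_accepts_symmetric_gaps(self):
        rng = np.random.default_rng(2)
        gaps = rng.choice([-1, 1], 10) * rng.uniform(0.2, 0.6, 10)
        assert sign_flip_pvalue(gaps) > 0.01


class TestAnnealing:
    def test_toy_quadratic_recovered(self):
        env = EnvironmentParams(n=10)
        ages = np.tile([0, 1], 10)
        target = 0.3
        obj = lambda v: -float(np.sum((v - target) ** 2))
        x, best, hist = optimal_allocation(env, ages, SAParams(seed=4), objective=obj)
        assert np.abs(x - target).max() < 1e-2

    def test_best_so_far_monotone_and_iterations_helpful(self):
        env = EnvironmentParams(b=20, beta=0.75, n=10)
        ages = np.r_[np.zeros(10, int), np.ones(10, int)]
        _, best, hist = optimal_allocation(env, ages, SAParams(iterations=4000, seed=7))
        assert np.all(np.diff(hist) >= 0)
        _, best2, _ = optimal_allocation(env, ages, SAParams(iterations=8000, seed=7))
        assert best2 >= hist[3999] - 1e-12

    def test_age_structure_shapes_the_optimum(self):
        """With a strong age cost differential the optimal allocation sends
        old workers foraging (low x) more than young ones; cross-checked
        against a 2-d grid search on a single 2-player group."""
        env = EnvironmentParams(b=20, r=1.0, beta=1.5, n=2)
        ages = np.array([1, 0])
        x, best, _ = optimal_allocation(env, ages, SAParams(iterations=20000, seed=2))
        assert x[0] < x[1]                        # the old member forages more
        # independent grid-search oracle at resolution 1e-3
        grid = np.linspace(0, 1, 1001)
        gx, gy = np.meshgrid(grid, grid, indexing="ij")
        e1 = gx + gy
        shared = 0.5 * (env.b * (2 - e1)) * (4 * (e1 / 2) * (1 - e1 / 2))
        c_old = (-(1 - gx) ** 2 + 2 * (1 - gx)) + env.r * gx
        c_young = (-(1 - gy) ** 2 + 2 * (1 - gy)) * np.exp(env.beta) + env.r * gy
        obj = shared - 0.5 * (c_old + c_young)
        i, j = np.unravel_index(obj.argmax(), obj.shape)
        assert best == pytest.approx(obj.max(), abs=2e-3)
        assert x[0] == pytest.approx(grid[i], abs=0.02)
        assert x[1] == pytest.approx(grid[j], abs=0.02)

    def test_zero_benefit_pure_cost_minimisation(self):
        """Without any benefit the optimum minimises pure cost; for r < 1
        full Task-1 engagement (cost r) beats full foraging (cost 1),
        verified against a 1-d grid search."""
        from polyethism.payoffs import BENEFIT0_FORMS
        BENEFIT0_FORMS["zero"] = lambda e, env: np.zeros_like(np.asarray(e, float))
        try:
            env = EnvironmentParams(b=1, r=0.5, beta=0.0, n=2, benefit0="zero")
            ages = np.array([0, 1])
            x, best, _ = optimal_allocation(env, ages, SAParams(iterations=20000, seed=3))
            grid = np.linspace(0, 1, 1001)
            cost = (-(1 - grid) ** 2 + 2 * (1 - grid)) + env.r * grid
            assert best == pytest.approx(-cost.min(), abs=1e-3)
            np.testing.assert_allclose(x, 1.0, atol=0.02)
        finally:
            BENEFIT0_FORMS.pop("zero")


class TestEfficiency:
    def test_trivial_ratios(self):
        traj = synthetic_traj(np.full((6, 4), 0.5), [0, 0, 1, 1],
                              payoff_rows=np.full((5, 4), 2.0))
        assert relative_efficiency(traj, 2.0, 0.2) == pytest.approx(1.0)
        assert relative_efficiency(traj, 4.0, 0.2) == pytest.approx(0.5)

    def test_nonpositive_optimum_flagged_undefined(self):
        traj = synthetic_traj(np.full((6, 4), 0.5), [0, 0, 1, 1],
                              payoff_rows=np.full((5, 4), 2.0))
        assert np.isnan(relative_efficiency(traj, 0.0, 0.2))
        assert np.isnan(relative_efficiency(traj, -1.0, 0.2))

    def test_mean_payoff_matches_engine_payoffs(self, rng):
        from polyethism.sl import group_payoff_vector
        env = EnvironmentParams(b=8, beta=0.4, n=5)
        x = rng.random(20)
        ages = np.tile([0, 1], 10)
        part = np.arange(20).reshape(4, 5)
        assert mean_payoff(x, ages, part, env) == pytest.approx(
            group_payoff_vector(x, ages, part, env).mean())


class TestSweep:
    def test_single_cell_sweep_row_fields(self):
        cfg = make_config(model="srt", T=100, N=20, environment={"n": 5})
        table = parameter_sweep([20.0], [0.5], [0.5], 1, cfg,
                                compute_efficiency=False)
        assert len(table) == 1
        row = table.iloc[0]
        assert row["error"] == ""
        assert row["regime"] in (REGULATION_FAILURE, BRANCHING_MIXED, AGE_POLYETHISM)
        assert 0.0 <= row["polyethism_index"] <= 1.0
        assert row["seed"] < 2**31

    def test_failed_cell_recorded_not_raised(self):
        cfg = make_config(model="srt", T=10, N=20, environment={"n": 5})
        table = parameter_sweep([-5.0], [0.0], [0.5], 1, cfg,
                                compute_efficiency=False)
        assert len(table) == 1
        assert "b must be > 0" in table.iloc[0]["error"]

    def test_replicates_get_distinct_seeds_and_modal_label(self):
        cfg = make_config(model="srt", T=150, N=20, environment={"n": 5})
        table = parameter_sweep([20.0], [0.75], [0.5], 3, cfg,
                                compute_efficiency=False)
        assert table["seed"].nunique() == 3
        agg = aggregate_regimes(table)
        assert len(agg) == 1
        assert agg.iloc[0]["replicates"] == 3
        assert isinstance(bool(agg.iloc[0]["regime_tie"]), bool)
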