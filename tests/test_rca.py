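import numpy as np
import pytest
from scipy import stats

from cgrm import synthetic
from cgrm.io import ExpressionSeries, RegulatorTargetMap
from cgrm.rca import (
    build_activity_profile,
    permutation_test,
    rca_analysis,
    run_rca,
    solve_interaction_strengths,
)
from tests.conftest import all_up_degs


def _expr(values):
    values = np.asarray(values, dtype=float)
    return ExpressionSeries(
        [f"G{i}" for i in range(values.shape[0])],
        np.arange(values.shape[1], dtype=float),
        values,
    )


class TestActivityProfile:
    def test_median_and_mean_summaries(self):
        expr = _expr([[1, 1], [2, 2], [9, 9]])
        maps = [RegulatorTargetMap("R", "miRNA", {"G0", "G1", "G2"})]
        med = build_activity_profile(expr, maps, method="median")
        np.testing.assert_allclose(med.z_values, [[2.0, 2.0]])
        mean = build_activity_profile(expr, maps, method="mean")
        np.testing.assert_allclose(mean.z_values, [[4.0, 4.0]])

    def test_single_target_profile_is_that_series(self):
        expr = _expr([[1, 5, 3], [9, 9, 9]])
        maps = [RegulatorTargetMap("R", "lncRNA", {"G0"})]
        prof = build_activity_profile(expr, maps)
        np.testing.assert_allclose(prof.z_values, [[1, 5, 3]])

    def test_regulator_without_measured_targets_named_in_error(self):
        expr = _expr([[1, 2]])
        maps = [RegulatorTargetMap("miR-x", "miRNA", {"ABSENT"})]
        with pytest.raises(ValueError, match="miR-x"):
            build_activity_profile(expr, maps)


class TestSolve:
    def test_identity_design_clamps_at_zero(self):
        z = np.eye(3)
        x = np.array([[1.0, -2.0, 3.0]])
        y, _ = solve_interaction_strengths(x, z)
        np.testing.assert_allclose(y, [[1.0, 0.0, 3.0]])

    def test_constant_single_row_gives_clamped_mean(self):
        z = np.ones((1, 4))
        x = np.array([[1.0, 2.0, 3.0, 6.0], [-1.0, -2.0, -3.0, -2.0]])
        y, _ = solve_interaction_strengths(x, z)
        np.testing.assert_allclose(y, [[3.0], [0.0]])

    def test_exact_factorization_recovered(self):
        rng = np.random.default_rng(1)
        z = rng.lognormal(0, 0.5, (4, 10))
        y0 = rng.uniform(0, 2, (25, 4))
        yh, resid = solve_interaction_strengths(y0 @ z, z)
        assert np.abs(yh - y0).max() < 1e-6
        assert resid < 1e-8

    def test_residual_never_worse_than_zero_solution(self):
        rng = np.random.default_rng(2)
        x = rng.normal(2, 1, (30, 8))
        z = rng.lognormal(0, 0.5, (3, 8))
        y, resid = solve_interaction_strengths(x, z)
        assert resid <= np.linalg.norm(x) + 1e-9

    def test_objective_invariant_to_regulator_order(self):
        rng = np.random.default_rng(3)
        x = rng.lognormal(1, 0.5, (20, 9))
        z = rng.lognormal(0, 0.5, (4, 9))
        perm = [2, 0, 3, 1]
        y1, r1 = solve_interaction_strengths(x, z)
        y2, r2 = solve_interaction_strengths(x, z[perm])
        assert r1 == pytest.approx(r2, abs=1e-9)
        np.testing.assert_allclose(y1[:, perm], y2, atol=1e-6)

    def test_sample_mismatch_rejected(self):
        with pytest.raises(ValueError, match="sample"):
            solve_interaction_strengths(np.ones((2, 5)), np.ones((1, 4)))


class TestPermutation:
    def test_add_one_smoothing_floor(self):
        # observed strength exceeding every permuted value -> p = 1/(n+1)
        rng = np.random.default_rng(0)
        z = np.linspace(1, 2, 8)[None, :]
        x = 10 * z + rng.normal(0, 0.01, (1, 8))
        obs, _ = solve_interaction_strengths(x, z)
        p = permutation_test(x, z, obs, n_perm=1000, seed=1)
        assert p[0, 0] == pytest.approx(1 / 1001)

    def test_single_permutation_bounds(self):
        rng = np.random.default_rng(4)
        x = rng.lognormal(0, 0.3, (20, 6))
        z = rng.lognormal(0, 0.3, (2, 6))
        obs, _ = solve_interaction_strengths(x, z)
        p = permutation_test(x, z, obs, n_perm=1, seed=0)
        assert set(np.round(np.unique(p), 6)) <= {0.5, 1.0}

    def test_deterministic_under_seed(self):
        rng = np.random.default_rng(5)
        x = rng.lognormal(0, 0.3, (10, 7))
        z = rng.lognormal(0, 0.3, (2, 7))
        obs, _ = solve_interaction_strengths(x, z)
        p1 = permutation_test(x, z, obs, n_perm=50, seed=9)
        p2 = permutation_test(x, z, obs, n_perm=50, seed=9)
        np.testing.assert_array_equal(p1, p2)

    def test_null_p_values_uniform_single_regulator(self):
        # held-out Z targets; analysed genes independent of Z -> exact null
        null = synthetic.generate_null_dataset(120, 12, seed=8)
        m = RegulatorTargetMap("R", "miRNA", set(null.gene_ids[:10]))
        res = rca_analysis(null, [m], gene_ids=null.gene_ids[10:],
                           n_perm=500, seed=8, log_scale=False, augment=False)
        ks = stats.kstest(res.p_values.ravel(), "uniform")
        assert ks.pvalue > 0.01


class TestRunRCA:
    def test_directions_separated_and_down_skipped_when_absent(self):
        truth = synthetic.make_ncrna_truth(n_genes=40, n_ncrnas=2, seed=5)
        expr, _, maps = synthetic.generate_expression(truth)
        degs = all_up_degs(expr.gene_ids)
        results = run_rca(expr, degs, maps, n_perm=20, seed=1)
        assert set(results) == {"up"}
        assert results["up"].direction_context == "up"
        assert results["up"].gene_ids == expr.gene_ids

    def test_circularity_flag_marks_z_building_targets(self):
        truth = synthetic.make_ncrna_truth(n_genes=30, n_ncrnas=2, seed=6)
        expr, _, maps = synthetic.generate_expression(truth)
        res = rca_analysis(expr, maps, n_perm=10, seed=0)
        for i, g in enumerate(res.gene_ids):
            for j, m in enumerate(maps):
                assert res.circular[i, j] == (g in m.target_gene_ids)

    def test_planted_regulator_recovery_small(self):
        from cgrm.benchmarks import auroc as roc_auc

        truth = synthetic.make_ncrna_truth(n_genes=120, n_ncrnas=4, seed=11)
        expr, _, maps = synthetic.generate_expression(truth)
        res = rca_analysis(expr, maps, n_perm=200, seed=11)
        planted = truth.planted_pairs()
        labels = np.array(
            [[(g, r) in planted for r in res.regulator_ids] for g in res.gene_ids]
        )
        assert roc_auc(labels.ravel(), res.strengths.ravel()) >= 0.9
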