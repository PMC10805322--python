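import numpy as np
import pytest
from scipy.stats import norm

from modelcongruence.deviance import (DegenerateScaleError, bootstrap_ci,
                                      ds_gene, ds_gene_matrix, ds_path,
                                      ds_path_pvalue, ds_pvalue, ds_sda,
                                      robust_center_scale, tumor_pathway_null)
from modelcongruence.data_io import ExpressionMatrix

from oracles import ds_path_oracle, ds_sda_oracle, median_, scaled_mad


class TestRobustCenterScale:
    def test_hand_computed(self):
        rcs = robust_center_scale(np.array([1, 2, 3, 4, 5.0]))
        assert rcs.mu_hat == 3.0
        assert rcs.s_hat == pytest.approx(1.4826)

    def test_all_identical_degenerate(self):
        rcs = robust_center_scale(np.array([2.0, 2.0, 2.0]))
        assert rcs.degenerate
        with pytest.raises(DegenerateScaleError):
            rcs.require_valid()

    def test_normal_consistency(self):
        x = np.random.default_rng(0).standard_normal(10000)
        rcs = robust_center_scale(x)
        assert rcs.s_hat == pytest.approx(1.0, rel=0.05)

    def test_sd_policy(self):
        x = np.random.default_rng(1).standard_normal(500)
        rcs = robust_center_scale(x, sigma_policy="sd")
        assert rcs.sigma_hat == pytest.approx(np.std(x, ddof=1))

    def test_too_few_values(self):
        with pytest.raises(ValueError, match="at least 3"):
            robust_center_scale(np.array([1.0, 2.0]))


class TestDsSda:
    def test_at_center_is_zero(self):
        rcs = robust_center_scale(np.array([1, 2, 3, 4, 5.0]))
        assert ds_sda(rcs.mu_hat, rcs) == 0.0

    def test_two_scale_units(self):
        rcs = robust_center_scale(np.array([1, 2, 3, 4, 5.0]))
        assert ds_sda(rcs.mu_hat + 2 * rcs.s_hat, rcs) == pytest.approx(2.0)

    def test_symmetry(self):
        rcs = robust_center_scale(np.array([1, 2, 3, 4, 5.0]))
        d = 1.7
        assert ds_sda(rcs.mu_hat + d, rcs) == ds_sda(rcs.mu_hat - d, rcs)

    def test_exact_grid(self):
        # planting at mu + d*s recovers d exactly
        rcs = robust_center_scale(np.random.default_rng(3).standard_normal(50))
        for d in [0.0, 0.5, 1.0, 2.0]:
            assert ds_sda(rcs.mu_hat + d * rcs.s_hat, rcs) == pytest.approx(d, abs=1e-12)

    def test_matches_oracle(self):
        rng = np.random.default_rng(5)
        proj = rng.standard_normal(31)
        rcs = robust_center_scale(proj)
        for c in [-2.0, 0.3, 1.9]:
            assert ds_sda(c, rcs) == pytest.approx(ds_sda_oracle(c, proj), abs=1e-12)


class TestDsPvalue:
    def test_at_center_is_one(self):
        rcs = robust_center_scale(np.array([1, 2, 3, 4, 5.0]))
        assert ds_pvalue(rcs.mu_hat, rcs) == pytest.approx(1.0)

    def test_normal_quantile(self):
        rcs = robust_center_scale(np.array([1, 2, 3, 4, 5.0]))
        c = rcs.mu_hat + 1.959964 * rcs.sigma_hat
        assert ds_pvalue(c, rcs) == pytest.approx(0.05, abs=1e-6)

    def test_strictly_decreasing(self):
        rcs = robust_center_scale(np.random.default_rng(0).standard_normal(100))
        grid = rcs.mu_hat + np.linspace(0, 4, 50) * rcs.sigma_hat
        ps = [ds_pvalue(c, rcs) for c in grid]
        assert np.all(np.diff(ps) < 0)

    def test_calibration_under_null(self):
        # tumor and model from the same N(0,1); rejection rate near alpha
        rng = np.random.default_rng(11)
        n_rep, n = 500, 200
        rejections = 0
        for _ in range(n_rep):
            rcs = robust_center_scale(rng.standard_normal(n))
            if ds_pvalue(rng.standard_normal(), rcs) < 0.05:
                rejections += 1
        assert 0.02 <= rejections / n_rep <= 0.08


class TestBootstrapCi:
    def test_brackets_population_value(self):
        rng = np.random.default_rng(2)
        proj = rng.standard_normal(10000)
        lo, hi = bootstrap_ci(2.0, proj, b=500, seed=0)
        assert lo < 2.0 < hi
        lo2, hi2 = bootstrap_ci(2.0, rng.standard_normal(100), b=500, seed=0)
        assert (hi - lo) < (hi2 - lo2)  # width shrinks with n

    def test_deterministic(self):
        proj = np.random.default_rng(3).standard_normal(80)
        assert bootstrap_ci(1.0, proj, seed=7) == bootstrap_ci(1.0, proj, seed=7)

    def test_percentile_rule_matches_replicates(self):
        proj = np.random.default_rng(4).standard_normal(60)
        (lo, hi), reps = bootstrap_ci(1.5, proj, b=1000, seed=1,
                                      return_replicates=True)
        logs = np.log2(reps)
        assert lo == pytest.approx(2 ** np.quantile(logs, 0.025), abs=1e-12)
        assert hi == pytest.approx(2 ** np.quantile(logs, 0.975), abs=1e-12)

    def test_coverage(self):
        # reduced-size version of the acceptance check
        rng = np.random.default_rng(9)
        n_sim, n = 120, 200
        hits = 0
        for i in range(n_sim):
            proj = rng.standard_normal(n)
            lo, hi = bootstrap_ci(2.0, proj, b=400, seed=i)
            hits += lo <= 2.0 <= hi  # population DS of c=2 vs N(0,1) is 2
        assert 0.88 <= hits / n_sim <= 1.0

    def test_all_degenerate_errors(self):
        with pytest.raises(DegenerateScaleError):
            bootstrap_ci(1.0, np.array([1.0, 1.0, 1.0, 1.0]), b=50, seed=0)


class TestDsGene:
    def test_at_median_zero(self):
        assert ds_gene(3.0, np.array([1, 2, 3, 4, 5.0])) == 0.0

    def test_plus_one_mad(self):
        assert ds_gene(3 + 1.4826, np.array([1, 2, 3, 4, 5.0])) == pytest.approx(1.0)

    def test_minus_two_mad(self):
        assert ds_gene(3 - 2 * 1.4826, np.array([1, 2, 3, 4, 5.0])) == pytest.approx(-2.0)

    def test_zero_mad_is_nan(self):
        assert np.isnan(ds_gene(1.0, np.array([2.0, 2.0, 2.0])))

    def test_matrix_matches_scalar(self):
        rng = np.random.default_rng(6)
        tv = rng.standard_normal((5, 9))
        mv = rng.standard_normal((5, 2))
        genes = [f"g{i}" for i in range(5)]
        tumor = ExpressionMatrix(genes, [f"t{j}" for j in range(9)], tv)
        models = ExpressionMatrix(genes, ["m0", "m1"], mv)
        mat = ds_gene_matrix(models, tumor)
        for i in range(5):
            for j in range(2):
                assert mat[i, j] == pytest.approx(ds_gene(mv[i, j], tv[i]), abs=1e-12)


class TestDsPath:
    def test_geometric_mean_identity(self):
        assert ds_path(np.array([1.0, 4.0])) == pytest.approx(2.0)

    def test_constant(self):
        assert ds_path(np.array([2.0, 2.0, 2.0])) == pytest.approx(2.0)

    def test_reciprocal_symmetry(self):
        assert ds_path(np.array([0.5, 2.0])) == pytest.approx(1.0)

    def test_sign_ignored(self):
        assert ds_path(np.array([-2.0, 2.0])) == pytest.approx(2.0)

    def test_zero_propagates(self):
        assert ds_path(np.array([0.0, 3.0])) == 0.0

    def test_nan_excluded_with_warning(self):
        with pytest.warns(UserWarning, match="excluding"):
            out = ds_path(np.array([np.nan, 2.0, 2.0]))
        assert out == pytest.approx(2.0)

    def test_empty_after_exclusion_errors(self):
        with pytest.warns(UserWarning):
            with pytest.raises(ValueError, match="no usable"):
                ds_path(np.array([np.nan]))

    def test_scale_equivariance(self, rng):
        devs = rng.standard_normal(12)
        assert ds_path(3.0 * devs) == pytest.approx(3.0 * ds_path(devs))

    def test_permutation_invariance(self, rng):
        devs = rng.standard_normal(12)
        assert ds_path(devs[::-1]) == pytest.approx(ds_path(devs))

    def test_bounded_by_min_max(self, rng):
        devs = rng.standard_normal(10)
        v = ds_path(devs)
        assert np.min(np.abs(devs)) <= v <= np.max(np.abs(devs))

    def test_matches_oracle(self, rng):
        devs = rng.standard_normal(8)
        assert ds_path(devs) == pytest.approx(ds_path_oracle(devs), abs=1e-12)


class TestDsPathPvalue:
    def test_below_all_nulls(self):
        assert ds_path_pvalue(0.1, np.array([1.0, 2.0, 3.0])) == 1.0

    def test_above_all_nulls_add_one(self):
        nulls = np.arange(1.0, 100.0)  # N = 99
        assert ds_path_pvalue(1000.0, nulls) == pytest.approx(1.0 / 100.0)

    def test_at_null_median(self):
        nulls = np.arange(1.0, 102.0)  # N = 101, median 51
        p = ds_path_pvalue(51.0, nulls)
        assert abs(p - 0.5) <= 1.0 / 102.0

    def test_empty_null_errors(self):
        with pytest.raises(ValueError, match="empty"):
            ds_path_pvalue(1.0, np.array([]))


class TestTumorPathwayNull:
    def test_loo_excludes_self(self):
        # a wild outlier sample must not shrink its own deviance via the MAD
        rng = np.random.default_rng(8)
        vals = rng.standard_normal((4, 20))
        vals[:, 0] += 50.0
        genes = [f"g{i}" for i in range(4)]
        tumor = ExpressionMatrix(genes, [f"t{j}" for j in range(20)], vals)
        null = tumor_pathway_null(tumor, genes)
        assert null[0] > 20.0
        assert np.median(null[1:]) < 3.0

    def test_matches_straight_line_recomputation(self):
        rng = np.random.default_rng(12)
        vals = rng.standard_normal((3, 10))
        genes = ["a", "b", "c"]
        tumor = ExpressionMatrix(genes, [f"t{j}" for j in range(10)], vals)
        null = tumor_pathway_null(tumor, genes)
        for j in range(10):
            devs = []
            for i in range(3):
                rest = [vals[i, jj] for jj in range(10) if jj != j]
                devs.append(abs((vals[i, j] - median_(rest)) / scaled_mad(rest)))
            assert null[j] == pytest.approx(ds_path_oracle(devs), abs=1e-10)
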