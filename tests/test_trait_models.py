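"""Tree-transformation model fitting: transforms, GLS and selection."""

import numpy as np
import pytest
from scipy import stats

from karyoevol.simulate import sim_bd_tree, sim_continuous
from karyoevol.trait_models import (
    aicc,
    fit_model,
    gls_fit,
    model_table,
    transform_covariance,
    transformed_vcv,
)
from karyoevol.trees import read_newick, vcv


class TestTransforms:
    def test_identity_parameters_return_base_covariance(self, bd_tree_50):
        _, C = vcv(bd_tree_50)
        for model, theta in [("lambda", 1.0), ("delta", 1.0), ("OU", 0.0)]:
            np.testing.assert_allclose(
                transform_covariance(C, model, theta), C, atol=1e-8)
        np.testing.assert_allclose(
            transformed_vcv(bd_tree_50, "kappa", 1.0), C, atol=1e-8)
        # OU at tiny alpha converges to C
        np.testing.assert_allclose(
            transform_covariance(C, "OU", 1e-9), C, atol=1e-6)

    def test_lambda_zero_is_star(self, bd_tree_50):
        _, C = vcv(bd_tree_50)
        out = transform_covariance(C, "lambda", 0.0)
        np.testing.assert_allclose(out - np.diag(np.diag(out)), 0.0)
        np.testing.assert_allclose(np.diag(out), np.diag(C))

    def test_ou_closed_form_two_tip(self):
        # height-1 two-tip tree at alpha = 2: V_ii = (1 - e^-4)/4,
        # V_ij = (1/4)(1 - e^0) e^{-4} = 0 since the tips share no path
        tree = read_newick("(A:1,B:1);")
        _, C = vcv(tree)
        V = transform_covariance(C, "OU", 2.0)
        alpha = 2.0
        expected_diag = (1 - np.exp(-2 * alpha * 1.0)) / (2 * alpha)
        assert V[0, 0] == pytest.approx(expected_diag, abs=1e-12)
        assert V[0, 1] == pytest.approx(0.0, abs=1e-12)

    def test_ou_requires_ultrametric(self):
        tree = read_newick("(A:1,B:2);")
        _, C = vcv(tree)
        with pytest.raises(ValueError, match="ultrametric"):
            transform_covariance(C, "OU", 1.0)


class TestGls:
    def test_star_tree_reduces_to_iid_normal(self):
        C = np.eye(3)
        y = np.array([1.0, 2.0, 3.0])
        root, sigma2, lnl = gls_fit(C, y)
        assert root == pytest.approx(2.0)
        assert sigma2 == pytest.approx(2.0 / 3.0)
        assert lnl == pytest.approx(
            stats.norm.logpdf(y, loc=2.0, scale=np.sqrt(sigma2)).sum())

    def test_constant_trait_is_degenerate(self):
        with pytest.raises(ValueError):
            gls_fit(np.eye(4), np.full(4, 3.0))

    @pytest.mark.parametrize("seed", range(5))
    def test_lnl_matches_dense_mvn_density(self, seed):
        tree = sim_bd_tree(12, 1.0, 0.2, seed=300 + seed)
        _, C = vcv(tree)
        y = sim_continuous(tree, "BM", seed=400 + seed)
        root, sigma2, lnl = gls_fit(C, y)
        dense = stats.multivariate_normal.logpdf(
            y, mean=np.full(y.size, root), cov=sigma2 * C)
        assert lnl == pytest.approx(dense, abs=1e-8)


class TestFitting:
    def test_lambda_one_nests_bm_with_aic_gap_of_two(self, bd_tree_50):
        y = sim_continuous(bd_tree_50, "BM", seed=8)
        bm = fit_model(bd_tree_50, y, "BM")
        lam = fit_model(bd_tree_50, y, "lambda")
        assert lam.theta == pytest.approx(1.0, abs=1e-4)
        assert lam.lnl == pytest.approx(bm.lnl, abs=1e-6)
        assert lam.aic - bm.aic == pytest.approx(2.0, abs=1e-5)

    def test_aicc_small_sample_identity(self):
        assert aicc(-36.610, k=2, n=26) == pytest.approx(77.741, abs=1e-3)

    def test_transformed_models_never_beat_bm_backwards(self, bd_tree_50):
        y = sim_continuous(bd_tree_50, "OU", seed=9, theta=1.0)
        fits = {f.model: f for f in model_table(bd_tree_50, y)}
        for name in ("lambda", "delta", "kappa", "OU"):
            assert fits[name].lnl >= fits["BM"].lnl - 1e-6
        assert min(f.delta_aicc for f in fits.values()) == 0.0

    def test_branch_scaling_rescales_sigma2_not_lnl(self):
        tree = sim_bd_tree(20, 1.0, seed=21)
        y = sim_continuous(tree, "BM", seed=22)
        bm = fit_model(tree, y, "BM")
        scaled = tree.copy()
        for node in scaled.postorder():
            node.length *= 4.0
        bm4 = fit_model(scaled, y, "BM")
        assert bm4.sigma2 == pytest.approx(bm.sigma2 / 4.0, rel=1e-8)
        assert bm4.lnl == pytest.approx(bm.lnl, abs=1e-8)

    def test_boundary_parameters_are_attainable(self):
        # strongly late-concentrated change pushes delta to its bound
        tree = sim_bd_tree(30, 1.0, seed=23)
        y = sim_continuous(tree, "delta", seed=24, theta=4.9)
        fit = fit_model(tree, y, "delta")
        assert 0 < fit.theta <= 5.0

    def test_delta_estimates_separate_early_from_late_burst(self):
        """The delta estimate is noisy and right-skewed on Yule trees,
        but it must separate early-concentrated (delta < 1) from
        late-concentrated (delta > 1) change: medians on either side
        of 1 for data simulated at delta = 0.3 vs 2.0."""
        early, late = [], []
        for rep in range(60):
            tree = sim_bd_tree(200, 1.0, seed=6000 + rep)
            y = sim_continuous(tree, "delta", seed=7000 + rep, theta=0.3)
            early.append(fit_model(tree, y, "delta").theta)
            y2 = sim_continuous(tree, "delta", seed=7500 + rep, theta=2.0)
            late.append(fit_model(tree, y2, "delta").theta)
        assert np.median(early) < 1.0 < np.median(late)
        assert np.median(early) <= 0.75  # computed calibration bound
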