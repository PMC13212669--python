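import math

import numpy as np
import pytest
from scipy import stats

from fsrselect.data_model import build_design, log_cpm
from fsrselect.voom import (
    LowessSmoother,
    VoomFit,
    ebayes_moderate,
    fit_linear_models,
    mean_log_count,
    moderated_tests_fixed,
    test_single_columns as _tsc,
    test_variable as _tv,
    voom_pipeline,
    voom_weights,
)


def _design(n, rng, p_extra=2):
    X = np.column_stack([np.ones(n), rng.standard_normal((n, p_extra))])
    return X


class TestWeightedLeastSquares:
    def test_exact_fit_recovers_coefficients(self, rng):
        X = _design(12, rng)
        b = np.array([[1.0, -2.0, 0.5], [0.0, 3.0, 1.0]])
        fit = fit_linear_models(b @ X.T, X)
        assert np.allclose(fit.beta, b, atol=1e-10)
        assert np.allclose(fit.sd, 0.0, atol=1e-8)

    def test_intercept_only_gives_weighted_mean(self, rng):
        y = rng.standard_normal((4, 9))
        w = rng.uniform(0.5, 2.0, size=y.shape)
        fit = fit_linear_models(y, np.ones((9, 1)), w)
        expected = (w * y).sum(axis=1) / w.sum(axis=1)
        assert np.allclose(fit.beta[:, 0], expected, atol=1e-12)

    def test_matches_brute_force_normal_equations(self, rng):
        X = _design(15, rng, p_extra=4)
        y = rng.standard_normal((30, 15))
        w = rng.uniform(0.2, 3.0, size=y.shape)
        fit = fit_linear_models(y, X, w)
        for g in range(y.shape[0]):
            W = np.diag(w[g])
            ref = np.linalg.solve(X.T @ W @ X, X.T @ W @ y[g])
            assert np.max(np.abs(fit.beta[g] - ref) / np.maximum(np.abs(ref), 1)) < 1e-10
            ref_dinv = np.diag(np.linalg.inv(X.T @ W @ X))
            assert np.allclose(fit.xtwx_inv_diag[g], ref_dinv, rtol=1e-9)

    def test_weight_scaling_equivariance(self, rng):
        X = _design(10, rng)
        y = rng.standard_normal((25, 10))
        w = rng.uniform(0.5, 2.0, size=y.shape)
        f1 = fit_linear_models(y, X, w)
        f2 = fit_linear_models(y, X, 7.3 * w)
        assert np.allclose(f1.beta, f2.beta, atol=1e-12)
        assert np.allclose(f1.fitted, f2.fitted, atol=1e-12)
        t1 = ebayes_moderate(f1)
        t2 = ebayes_moderate(f2)
        p1 = _tv(f1, t1, np.array([1]))
        p2 = _tv(f2, t2, np.array([1]))
        assert np.allclose(p1, p2, atol=1e-10)

    def test_rank_deficient_design_rejected(self, rng):
        X = np.column_stack([np.ones(6), np.ones(6)])
        with pytest.raises(ValueError, match="rank"):
            fit_linear_models(rng.standard_normal((3, 6)), X)

    def test_zero_residual_df_rejected(self, rng):
        X = np.eye(3)
        with pytest.raises(ValueError, match="degrees of freedom"):
            fit_linear_models(rng.standard_normal((2, 3)), X)


class TestMeanLogCount:
    def test_equals_mean_log_counts_exactly(self, small_sim):
        sc, cm = small_sim
        y = log_cpm(cm).y
        direct = np.log2(cm.counts + 0.5).mean(axis=1)
        assert np.allclose(mean_log_count(y, cm.libsize), direct, atol=1e-10)

    def test_offsets_cancel_when_libsize_is_million(self):
        y = np.full((3, 4), 2.5)
        out = mean_log_count(y, np.full(4, 1e6 - 1.0))
        assert np.allclose(out, 2.5, atol=1e-12)

    def test_single_sample(self):
        out = mean_log_count(np.array([[1.0]]), np.array([99.0]))
        assert out[0] == pytest.approx(1.0 + np.log2(100.0) - np.log2(1e6))


class TestVoomWeights:
    def test_constant_trend_gives_sixteenth(self, rng):
        n, G = 6, 20
        fit = VoomFit(
            y=np.zeros((G, n)), X=np.ones((n, 1)), beta=np.zeros((G, 1)),
            sd=np.full(G, 4.0), df_resid=n - 1, fitted=rng.normal(5, 1, (G, n)),
            weights=np.ones((G, n)), xtwx_inv_diag=np.ones((G, 1)),
            mean_logcount=np.linspace(2, 8, G),
        )
        w = voom_weights(fit, libsize=np.full(n, 1e5))
        # sqrt(sd) = 2 everywhere, so the trend is 2 and w = 2^-4
        assert np.allclose(w, 0.0625, atol=1e-12)

    def test_weights_positive_and_finite(self, small_sim):
        sc, cm = small_sim
        y = log_cpm(cm).y
        X, _ = build_design(sc.design, sc.design.candidate_names)
        fit = fit_linear_models(y, X)
        fit.mean_logcount = mean_log_count(y, cm.libsize)
        w = voom_weights(fit, cm.libsize)
        assert np.all(w > 0) and np.all(np.isfinite(w))

    def test_decreasing_trend_upweights_abundant_observations(self, small_sim):
        # the simulator's truth has sd decreasing with abundance, so fitted
        # log-count and weight should be positively associated
        sc, cm = small_sim
        y = log_cpm(cm).y
        X, _ = build_design(sc.design, sc.design.candidate_names)
        fit, _ = voom_pipeline(y, cm.libsize, X)
        logcount = fit.fitted + (np.log2(cm.libsize + 1) - np.log2(1e6))
        rho = stats.spearmanr(logcount.ravel(), fit.weights.ravel()).statistic
        assert rho > 0

    def test_too_few_genes_rejected(self, rng):
        fit = fit_linear_models(rng.standard_normal((5, 8)), np.ones((8, 1)))
        fit.mean_logcount = np.arange(5.0)
        with pytest.raises(ValueError, match="10 genes"):
            voom_weights(fit, np.full(8, 100.0))


class TestLowessSmoother:
    def test_matches_statsmodels_reference(self, rng):
        from statsmodels.nonparametric.smoothers_lowess import lowess as sm_lowess

        x = rng.uniform(0, 10, 400)
        y = np.sin(x / 2) + 0.2 * x + rng.normal(0, 0.15, 400)
        xa, fa = LowessSmoother(x, frac=0.5, iterations=3).fit(y)
        ref = sm_lowess(
            y, x, frac=0.5, it=3, delta=0.01 * np.ptp(x), return_sorted=True
        )
        diff = np.abs(np.interp(ref[:, 0], xa, fa) - ref[:, 1])
        assert diff.max() < 0.05 * np.std(y)

    def test_reproduces_a_line_exactly(self):
        x = np.linspace(0, 1, 60)
        y = 2.0 + 3.0 * x
        xa, fa = LowessSmoother(x, frac=0.5, iterations=3).fit(y)
        assert np.allclose(fa, 2.0 + 3.0 * xa, atol=1e-10)


class TestEmpiricalBayes:
    def test_identical_variances_give_degenerate_prior(self, rng):
        fit = fit_linear_models(rng.standard_normal((5, 8)), np.ones((8, 1)))
        fit.sd = np.full(5, 2.0)
        mt = ebayes_moderate(fit)
        assert math.isinf(mt.d0)
        assert mt.s0sq == pytest.approx(4.0)
        assert np.allclose(mt.s_tilde_sq, 4.0)

    def test_no_shrinkage_limit(self, rng):
        fit = fit_linear_models(rng.standard_normal((6, 9)), np.ones((9, 1)))
        mt = moderated_tests_fixed(fit, d0=0.0, s0sq=1.0)
        assert np.allclose(mt.s_tilde_sq, fit.sd**2, atol=1e-14)
        assert mt.df_total == fit.df_resid

    def test_recovers_simulated_prior(self):
        rng = np.random.default_rng(11)
        G, df, d0, s0sq = 5000, 10, 4.0, 1.0
        sigma2 = s0sq * d0 / rng.chisquare(d0, G)
        s2 = sigma2 * rng.chisquare(df, G) / df

        fit = fit_linear_models(
            np.zeros((G, df + 1)) + rng.standard_normal((G, df + 1)),
            np.ones((df + 1, 1)),
        )
        fit.sd = np.sqrt(s2)
        mt = ebayes_moderate(fit)
        assert abs(mt.d0 - d0) / d0 < 0.25
        assert abs(mt.s0sq - s0sq) / s0sq < 0.10


class TestModeratedTests:
    def test_zero_coefficient_gives_p_one(self, rng):
        X = _design(10, rng)
        fit = fit_linear_models(rng.standard_normal((12, 10)), X)
        fit.beta[:, 1] = 0.0  # an exactly-zero estimate must give stat 0, p = 1
        mt = ebayes_moderate(fit)
        p = _tv(fit, mt, np.array([1]))
        assert np.all(p == 1.0)

    def test_classical_t_in_no_shrinkage_limit(self, rng):
        X = _design(14, rng, p_extra=2)
        y = rng.standard_normal((40, 14))
        fit = fit_linear_models(y, X)
        mt = moderated_tests_fixed(fit, d0=0.0, s0sq=1.0)
        p = _tv(fit, mt, np.array([2]))
        xtx_inv = np.linalg.inv(X.T @ X)
        for g in range(y.shape[0]):
            bhat = xtx_inv @ X.T @ y[g]
            resid = y[g] - X @ bhat
            s2 = resid @ resid / (14 - 3)
            t = bhat[2] / np.sqrt(s2 * xtx_inv[2, 2])
            ref = 2 * stats.t.sf(abs(t), 14 - 3)
            assert abs(p[g] - ref) < 1e-8

    def test_f_block_matches_classical_anova(self, rng):
        X = _design(16, rng, p_extra=3)
        y = rng.standard_normal((25, 16))
        fit = fit_linear_models(y, X)
        mt = moderated_tests_fixed(fit, d0=0.0, s0sq=1.0)
        block = np.array([2, 3])
        p = _tv(fit, mt, block)
        Xr = X[:, [0, 1]]
        for g in range(5):
            rss_f = np.sum((y[g] - X @ np.linalg.lstsq(X, y[g], rcond=None)[0]) ** 2)
            rss_r = np.sum((y[g] - Xr @ np.linalg.lstsq(Xr, y[g], rcond=None)[0]) ** 2)
            F = ((rss_r - rss_f) / 2) / (rss_f / (16 - 4))
            ref = stats.f.sf(F, 2, 16 - 4)
            assert abs(p[g] - ref) < 1e-8

    def test_intercept_block_rejected(self, small_sim, rng):
        X = _design(10, rng)
        fit = fit_linear_models(rng.standard_normal((12, 10)), X)
        mt = ebayes_moderate(fit)
        with pytest.raises(ValueError, match="intercept"):
            _tv(fit, mt, np.array([0]))

    def test_single_column_batch_agrees_with_per_column(self, rng):
        X = _design(12, rng, p_extra=3)
        y = rng.standard_normal((30, 12))
        fit = fit_linear_models(y, X, rng.uniform(0.5, 2, y.shape))
        mt = ebayes_moderate(fit)
        batch = _tsc(fit, mt, np.array([1, 2, 3]))
        for j, col in enumerate([1, 2, 3]):
            assert np.allclose(batch[:, j], _tv(fit, mt, np.array([col])))


class TestLimmaOracle:
    def test_pipeline_matches_r_limma_voom(self, tmp_path, small_sim):
        """Independent oracle: R limma's voom + eBayes on the same inputs."""
        import subprocess

        import pandas as pd

        sc, cm = small_sim
        X, blocks = build_design(sc.design, sc.design.candidate_names)
        pd.DataFrame(cm.counts, index=list(cm.gene_ids), columns=list(cm.sample_ids)).to_csv(
            tmp_path / "counts.csv"
        )
        pd.DataFrame(X).to_csv(tmp_path / "design.csv", index=False)
        np.savetxt(tmp_path / "libsize.txt", cm.libsize)
        script = tmp_path / "oracle.R"
        script.write_text(
            'suppressMessages(library(limma))\n'
            'counts <- as.matrix(read.csv("counts.csv", row.names=1))\n'
            'X <- as.matrix(read.csv("design.csv"))\n'
            'lib <- scan("libsize.txt")\n'
            'v <- voom(counts, design=X, lib.size=lib)\n'
            'fit <- eBayes(lmFit(v, X))\n'
            'write.table(v$weights, "r_weights.txt", row.names=FALSE, col.names=FALSE)\n'
            'write.table(fit$p.value[,2], "r_p.txt", row.names=FALSE, col.names=FALSE)\n'
            'cat(fit$df.prior, fit$s2.prior, "\\n", file="r_prior.txt")\n'
        )
        subprocess.run(["Rscript", "oracle.R"], cwd=tmp_path, check=True, capture_output=True)
        y = log_cpm(cm).y
        fit, tests = voom_pipeline(y, cm.libsize, X)
        p = _tv(fit, tests, blocks[sc.design.primary_names[0]])
        r_w = np.loadtxt(tmp_path / "r_weights.txt")
        r_p = np.loadtxt(tmp_path / "r_p.txt")
        r_prior = np.loadtxt(tmp_path / "r_prior.txt")
        assert np.max(np.abs(fit.weights - r_w) / r_w) < 0.02
        assert np.max(np.abs(p - r_p)) < 5e-3
        assert tests.d0 == pytest.approx(r_prior[0], rel=0.05)
        assert tests.s0sq == pytest.approx(r_prior[1], rel=0.05)
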