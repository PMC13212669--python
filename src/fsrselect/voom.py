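"""Per-gene weighted linear models with voom precision weights and
empirical-Bayes moderated t/F statistics.

The pipeline is: (1) unweighted least squares on log-CPM values per gene;
(2) a LOWESS fit of the quarter-root residual standard deviation against
mean log-count gives the mean-variance trend; (3) each observation's
precision weight is the trend evaluated at its fitted log-count, raised
to the -4 power; (4) a single weighted refit, followed by shrinkage of
the per-gene variances toward a scaled-F prior (d0, s0^2) estimated by
moment matching on log(s^2), and moderated t / F tests per variable.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import special

from ._kernels import chol_solve_diag, lowess_fit
from .data_model import LOG2_MILLION

__all__ = [
    "VoomFit",
    "ModeratedTests",
    "fit_linear_models",
    "mean_log_count",
    "voom_weights",
    "ebayes_moderate",
    "test_variable",
    "voom_pipeline",
]


@dataclass
class VoomFit:
    """Per-gene weighted least-squares fit shared by the test machinery."""

    y: np.ndarray            # G × n responses (log-CPM)
    X: np.ndarray            # n × p design
    beta: np.ndarray         # G × p coefficient estimates
    sd: np.ndarray           # per-gene residual standard deviation
    df_resid: int            # n - rank(X)
    fitted: np.ndarray       # G × n fitted values
    weights: np.ndarray      # G × n precision weights (ones if unweighted)
    xtwx_inv_diag: np.ndarray  # G × p diagonal of (X'WX)^{-1}
    mean_logcount: np.ndarray | None = None  # per-gene c~_g (set by the pipeline)

    @property
    def n_genes(self) -> int:
        return self.y.shape[0]


@dataclass
class ModeratedTests:
    """Empirical-Bayes variance shrinkage scaffolding.

    s_tilde_sq_g = (d0*s0sq + df*s_g^2) / (d0 + df), with the d0 = inf
    limit equal to s0sq and the d0 = 0 limit equal to s_g^2.
    """

    d0: float
    s0sq: float
    s_tilde_sq: np.ndarray
    df_total: float  # df_resid + d0 (inf allowed)


def fit_linear_models(
    y: np.ndarray, X: np.ndarray, w: np.ndarray | None = None,
    check_rank: bool = True,
) -> VoomFit:
    """Weighted least squares per gene: beta = (X'WX)^{-1} X'W y.

    ``w`` is a G × n matrix of positive observation weights; when absent the
    ordinary least-squares fit is computed with a single shared projector.
    """
    y = np.asarray(y, dtype=float)
    X = np.asarray(X, dtype=float)
    G, n = y.shape
    p = X.shape[1]
    if check_rank and np.linalg.matrix_rank(X) < p:
        raise ValueError("design matrix is rank-deficient")
    df = n - p
    if df < 1:
        raise ValueError("no residual degrees of freedom (n - rank(X) = 0)")
    if w is None:
        xtx_inv = np.linalg.inv(X.T @ X)
        beta = y @ (X @ xtx_inv)           # G × p
        fitted = beta @ X.T
        resid = y - fitted
        rss = np.einsum("gi,gi->g", resid, resid)
        dinv = np.broadcast_to(np.diag(xtx_inv), (G, p))
        weights = np.ones_like(y)
    else:
        w = np.asarray(w, dtype=float)
        if w.shape != y.shape or np.any(w <= 0) or not np.all(np.isfinite(w)):
            raise ValueError("weights must be positive, finite, and G × n")
        # X' W X assembled as w @ (x_k x_k' outer products): one large GEMM
        outer = (X[:, :, None] * X[:, None, :]).reshape(n, p * p)
        xtwx = (w @ outer).reshape(G, p, p)
        xtwy = (w * y) @ X
        beta, dinv = chol_solve_diag(xtwx, xtwy)
        fitted = beta @ X.T
        resid = y - fitted
        rss = np.einsum("gi,gi->g", w * resid, resid)
        weights = w
    sd = np.sqrt(np.maximum(rss, 0.0) / df)
    return VoomFit(
        y=y, X=X, beta=beta, sd=sd, df_resid=df, fitted=fitted,
        weights=weights, xtwx_inv_diag=dinv,
    )


def mean_log_count(y: np.ndarray, libsize: np.ndarray) -> np.ndarray:
    """c~_g = mean_i y_gi + mean_i log2(R_i + 1) - log2(1e6)."""
    libsize = np.asarray(libsize, dtype=float)
    return np.asarray(y, dtype=float).mean(axis=1) + np.log2(libsize + 1.0).mean() - LOG2_MILLION


_WEIGHT_TREND_FLOOR = 1e-6


class LowessSmoother:
    """Robust locally weighted linear regression with a fixed x vector.

    Tricube-weighted local linear fits at anchor points (points more than
    ``delta`` apart, interpolated in between, as in the classical lowess
    delta speed-up), followed by ``iterations`` bisquare robustness
    re-weightings.  The x-dependent neighborhoods and kernel weights are
    precomputed, so smoothing many different y vectors against the same x
    (as the backward-selection loop does with the mean log-counts) costs a
    handful of vectorized reductions per call.
    """

    def __init__(
        self,
        x: np.ndarray,
        frac: float = 0.5,
        iterations: int = 3,
        delta: float | None = None,
    ):
        x = np.asarray(x, dtype=float)
        n = x.size
        if n < 2:
            raise ValueError("need at least two points")
        self.order = np.argsort(x, kind="stable")
        xs = x[self.order]
        self.xs = xs
        self.iterations = iterations
        k = max(2, min(n, int(frac * n + 1e-9)))
        if delta is None:
            delta = 0.01 * (xs[-1] - xs[0])
        # anchors: first point, then next point > previous anchor + delta, last point
        anchors = [0]
        for i in range(1, n):
            if xs[i] > xs[anchors[-1]] + delta:
                anchors.append(i)
        if anchors[-1] != n - 1:
            anchors.append(n - 1)
        self.anchors = np.asarray(anchors)
        A = len(anchors)
        idx = np.empty((A, k), dtype=np.intp)
        for a, i in enumerate(anchors):
            lo = min(max(0, i - k // 2), n - k)
            hi = lo + k
            # slide the window to the k nearest neighbours of xs[i]
            while lo > 0 and xs[i] - xs[lo - 1] < xs[hi - 1] - xs[i]:
                lo -= 1
                hi -= 1
            while hi < n and xs[hi] - xs[i] < xs[i] - xs[lo]:
                lo += 1
                hi += 1
            idx[a] = np.arange(lo, hi)
        self.idx = np.ascontiguousarray(idx)
        self.xw = np.ascontiguousarray(xs[idx])                      # A × k neighbour abscissae
        d = np.abs(self.xw - xs[self.anchors][:, None])
        h = d.max(axis=1, keepdims=True)
        with np.errstate(invalid="ignore", divide="ignore"):
            u = np.where(h > 0, d / h, 0.0)
        self.tricube = np.ascontiguousarray(np.clip(1.0 - u**3, 0.0, None) ** 3)

    def fit(self, y: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Smooth y (original order); returns (anchor x, anchor fit)."""
        ys = np.ascontiguousarray(np.asarray(y, dtype=float)[self.order])
        xa = self.xs[self.anchors]
        fit_a = lowess_fit(
            ys, self.idx, self.tricube, self.xw, xa, self.xs, self.iterations
        )
        return xa, fit_a


def voom_weights(
    fit: VoomFit,
    libsize: np.ndarray,
    span: float = 0.5,
    iterations: int = 3,
    smoother: LowessSmoother | None = None,
) -> np.ndarray:
    """Precision weights from the LOWESS mean-variance trend.

    Fits lo(.): sqrt(s_g) on c~_g, then w_gi = lo(yhat_gi + log2(R_i+1)
    - log2(1e6))^{-4}.  The trend is evaluated by linear interpolation with
    constant extrapolation beyond the observed c~ range, and floored at a
    small positive value before the -4 power.
    """
    if fit.n_genes < 10:
        raise ValueError("need at least 10 genes to fit the mean-variance trend")
    ctilde = fit.mean_logcount
    if ctilde is None:
        ctilde = mean_log_count(fit.y, libsize)
    if smoother is None:
        smoother = LowessSmoother(ctilde, frac=span, iterations=iterations)
    xs, ys = smoother.fit(np.sqrt(fit.sd))
    offsets = np.log2(np.asarray(libsize, dtype=float) + 1.0) - LOG2_MILLION
    fitted_logcount = fit.fitted + offsets[None, :]
    trend = np.interp(fitted_logcount, xs, ys)
    trend = np.maximum(trend, _WEIGHT_TREND_FLOOR)
    return trend ** -4.0


from functools import lru_cache


@lru_cache(maxsize=None)
def _df_constants(df: float) -> tuple[float, float, float]:
    return (
        float(special.digamma(df / 2.0)),
        math.log(df / 2.0),
        float(special.polygamma(1, df / 2.0)),
    )


def _trigamma_inverse(y: float) -> float:
    """Solve trigamma(x) = y for x > 0 by Newton iteration."""
    if y <= 0:
        return math.inf
    if y > 1e7:
        return 1.0 / math.sqrt(y)
    if y < 1e-6:
        return 1.0 / y
    x = 0.5 + 1.0 / y
    for _ in range(50):
        tri = special.polygamma(1, x)
        dif = tri * (1.0 - tri / y) / special.polygamma(2, x)
        x += dif
        if -dif / x < 1e-10:
            break
    return float(x)


def ebayes_moderate(fit: VoomFit) -> ModeratedTests:
    """Estimate the scaled-F prior (d0, s0sq) and the shrunken variances.

    Moment matching on z = log(s^2): z - digamma(df/2) + log(df/2) has mean
    log(sigma0^2) + digamma(d0/2) - log(d0/2) and excess variance
    trigamma(d0/2); non-positive excess variance gives d0 = inf.
    """
    df = fit.df_resid
    s2 = fit.sd ** 2
    usable = s2 > 0
    if usable.sum() < 2:
        raise ValueError("need at least 2 genes with positive residual variance")
    s2u = s2[usable]
    if np.allclose(s2u, s2u[0], rtol=1e-12, atol=0.0):
        # degenerate prior: no between-gene variability at all
        d0, s0sq = math.inf, float(s2u[0])
    else:
        dig, logh, tri = _df_constants(df)
        z = np.log(s2u)
        e = z - dig + logh
        emean = float(e.mean())
        evar = float(e.var(ddof=1)) - tri
        if evar <= 0:
            d0, s0sq = math.inf, float(math.exp(emean))
        else:
            half_d0 = _trigamma_inverse(evar)
            d0 = 2.0 * half_d0
            s0sq = float(
                math.exp(emean + special.digamma(half_d0) - math.log(half_d0))
            )
    if math.isinf(d0):
        s_tilde_sq = np.full_like(s2, s0sq)
    else:
        s_tilde_sq = (d0 * s0sq + df * s2) / (d0 + df)
    return ModeratedTests(d0=d0, s0sq=s0sq, s_tilde_sq=s_tilde_sq, df_total=d0 + df)


def moderated_tests_fixed(fit: VoomFit, d0: float, s0sq: float) -> ModeratedTests:
    """Build ModeratedTests with a fixed prior (d0 = 0 gives classical tests)."""
    s2 = fit.sd ** 2
    if d0 == 0:
        s_tilde_sq = s2.copy()
    elif math.isinf(d0):
        s_tilde_sq = np.full_like(s2, s0sq)
    else:
        s_tilde_sq = (d0 * s0sq + fit.df_resid * s2) / (d0 + fit.df_resid)
    return ModeratedTests(d0=d0, s0sq=s0sq, s_tilde_sq=s_tilde_sq, df_total=d0 + fit.df_resid)


_P_FLOOR = np.nextafter(0.0, 1.0)


def test_variable(
    fit: VoomFit, tests: ModeratedTests, block: np.ndarray
) -> np.ndarray:
    """Per-gene two-sided p-values for one variable's coefficient block.

    A single-column block uses a moderated t with d0 + df residual degrees
    of freedom; a multi-column block uses a moderated F comparing the full
    fit against the fit with the block dropped, with the shrunken variance
    in the denominator.
    """
    block = np.atleast_1d(np.asarray(block, dtype=int))
    if block.size == 0:
        raise ValueError("empty coefficient block")
    if np.any(block == 0):
        raise ValueError("the intercept column cannot be tested")
    if np.any(block < 0) or np.any(block >= fit.X.shape[1]):
        raise ValueError("block indices out of range")
    df = tests.df_total
    if block.size == 1:
        t = moderated_t(fit, tests, block)[:, 0]
        if math.isinf(df):
            p = 2.0 * special.ndtr(-np.abs(t))
        else:
            p = 2.0 * special.stdtr(df, -np.abs(t))
    else:
        F = moderated_f(fit, tests, block)
        q = block.size
        if math.isinf(df):
            p = special.chdtrc(q, q * F)
        else:
            p = special.fdtrc(q, df, F)
    return np.clip(p, _P_FLOOR, 1.0)


def moderated_t(fit: VoomFit, tests: ModeratedTests, cols: np.ndarray) -> np.ndarray:
    """Moderated t statistics (G × C) for single-column coefficient blocks."""
    cols = np.atleast_1d(np.asarray(cols, dtype=int))
    if np.any(cols == 0):
        raise ValueError("the intercept column cannot be tested")
    var = tests.s_tilde_sq[:, None] * fit.xtwx_inv_diag[:, cols]
    b = fit.beta[:, cols]
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(b == 0, 0.0, b / np.sqrt(var))
        t = np.where(np.isfinite(t), t, np.where(b == 0, 0.0, np.sign(b)) * np.inf)
    return t


def moderated_f(fit: VoomFit, tests: ModeratedTests, block: np.ndarray) -> np.ndarray:
    """Moderated F statistics for one multi-column block (full vs dropped fit)."""
    block = np.asarray(block, dtype=int)
    keep = np.setdiff1d(np.arange(fit.X.shape[1]), block)
    sub = fit_linear_models(fit.y, fit.X[:, keep], _weights_or_none(fit), check_rank=False)
    rss_full = fit.sd ** 2 * fit.df_resid
    rss_red = sub.sd ** 2 * sub.df_resid
    q = block.size
    with np.errstate(divide="ignore", invalid="ignore"):
        F = (rss_red - rss_full) / (q * tests.s_tilde_sq)
    return np.where(np.isfinite(F), np.maximum(F, 0.0), np.inf)


def test_single_columns(
    fit: VoomFit, tests: ModeratedTests, cols: np.ndarray
) -> np.ndarray:
    """Moderated-t p-values for several single-column blocks at once (G × C)."""
    t = moderated_t(fit, tests, cols)
    df = tests.df_total
    if math.isinf(df):
        p = 2.0 * special.ndtr(-np.abs(t))
    else:
        p = 2.0 * special.stdtr(df, -np.abs(t))
    return np.clip(p, _P_FLOOR, 1.0)


def _weights_or_none(fit: VoomFit) -> np.ndarray | None:
    w = fit.weights
    if np.all(w == w.flat[0]):
        return None
    return w


def voom_pipeline(
    y: np.ndarray,
    libsize: np.ndarray,
    X: np.ndarray,
    span: float = 0.5,
    smoother: LowessSmoother | None = None,
    check_rank: bool = True,
) -> tuple[VoomFit, ModeratedTests]:
    """Run the full pipeline: unweighted pass, weights, weighted refit, shrinkage.

    ``smoother`` may carry a precomputed LowessSmoother for the dataset's
    mean log-counts (they do not depend on the design), which the
    backward-selection loop exploits to avoid re-deriving neighborhoods.
    """
    first = fit_linear_models(y, X, check_rank=check_rank)
    first.mean_logcount = mean_log_count(y, libsize)
    w = voom_weights(first, libsize, span=span, smoother=smoother)
    fit = fit_linear_models(y, X, w, check_rank=False)
    fit.mean_logcount = first.mean_logcount
    tests = ebayes_moderate(fit)
    return fit, tests
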