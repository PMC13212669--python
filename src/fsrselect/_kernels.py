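"""Compiled inner loop for the per-gene weighted least-squares solves.

The backward-selection procedure refits thousands of small weighted linear
models (one per gene, per candidate model, per pseudo-augmentation).  The
normal equations are assembled with batched BLAS in the caller; this kernel
fuses the per-gene Cholesky factorization, coefficient solve, and
inverse-diagonal extraction to avoid per-matrix LAPACK dispatch overhead.
"""

from __future__ import annotations

import numba
import numpy as np


@numba.njit(cache=True)
def lowess_fit(ys, idx, tric, xw, xa, xs, iterations):  # pragma: no cover
    """Robust local linear smoothing with precomputed neighborhoods.

    ys: responses in sorted-x order; idx/tric/xw: per-anchor neighbor
    indices, tricube weights, and abscissae; xa: anchor x; xs: all x
    (sorted).  Returns the fit at the anchors after ``iterations``
    bisquare robustness re-weightings.
    """
    n = ys.size
    A, k = idx.shape
    rw = np.ones(n)
    fa = np.empty(A)
    resid = np.empty(n)
    for it in range(iterations + 1):
        for a in range(A):
            sw = 0.0
            swx = 0.0
            swxx = 0.0
            swy = 0.0
            swxy = 0.0
            for m in range(k):
                j = idx[a, m]
                wgt = tric[a, m] * rw[j]
                x = xw[a, m]
                yv = ys[j]
                sw += wgt
                swx += wgt * x
                swxx += wgt * x * x
                swy += wgt * yv
                swxy += wgt * x * yv
            denom = swxx * sw - swx * swx
            slope = (swxy * sw - swx * swy) / denom if denom > 0.0 else 0.0
            inter = (swy - slope * swx) / sw if sw > 0.0 else 0.0
            fa[a] = inter + slope * xa[a]
        if it == iterations:
            break
        # residuals via linear interpolation of the anchor fit onto xs
        a2 = 0
        for i in range(n):
            x = xs[i]
            while a2 < A - 2 and xa[a2 + 1] < x:
                a2 += 1
            if x <= xa[0]:
                yh = fa[0]
            elif x >= xa[A - 1]:
                yh = fa[A - 1]
            else:
                x0 = xa[a2]
                x1 = xa[a2 + 1]
                yh = (
                    fa[a2] + (fa[a2 + 1] - fa[a2]) * (x - x0) / (x1 - x0)
                    if x1 > x0
                    else fa[a2]
                )
            resid[i] = ys[i] - yh
        s = np.median(np.abs(resid))
        if s <= 0.0:
            break
        for i in range(n):
            u = resid[i] / (6.0 * s)
            if u < -1.0:
                u = -1.0
            elif u > 1.0:
                u = 1.0
            rw[i] = (1.0 - u * u) ** 2
    return fa


@numba.njit(cache=True)
def chol_solve_diag(M, v):  # pragma: no cover - exercised via fit_linear_models
    """For each gene g solve M[g] beta = v[g] and return diag(M[g]^{-1}).

    M is G × p × p (symmetric positive definite normal-equation matrices),
    v is G × p.  Raises if any matrix is not positive definite.
    """
    G, p, _ = M.shape
    beta = np.empty((G, p))
    dinv = np.empty((G, p))
    L = np.empty((p, p))
    z = np.empty(p)
    u = np.empty(p)
    for g in range(G):
        # Cholesky M = L L' (lower)
        for i in range(p):
            for j in range(i, p):
                s = M[g, i, j]
                for m in range(i):
                    s -= L[i, m] * L[j, m]
                if i == j:
                    if s <= 0.0:
                        raise np.linalg.LinAlgError(
                            "normal-equation matrix not positive definite"
                        )
                    L[i, i] = np.sqrt(s)
                else:
                    L[j, i] = s / L[i, i]
        # beta: solve L z = v, then L' beta = z
        for i in range(p):
            s = v[g, i]
            for m in range(i):
                s -= L[i, m] * z[m]
            z[i] = s / L[i, i]
        for i in range(p - 1, -1, -1):
            s = z[i]
            for m in range(i + 1, p):
                s -= L[m, i] * beta[g, m]
            beta[g, i] = s / L[i, i]
        # diag of M^{-1}: for each j solve L u = e_j; diag_j = ||u||^2
        for j in range(p):
            u[j] = 1.0 / L[j, j]
            for i in range(j + 1, p):
                s = 0.0
                for m in range(j, i):
                    s -= L[i, m] * u[m]
                u[i] = s / L[i, i]
            s = 0.0
            for i in range(j, p):
                s += u[i] * u[i]
            dinv[g, j] = s
    return beta, dinv
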