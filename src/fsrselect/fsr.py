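"""False-selection-rate control via pseudo-variable augmentation.

The backward-elimination path over the real candidates is augmented B
times with k_P pseudo-variables that are irrelevant by construction.  The
propensity of the path to retain pseudo-variables at a threshold lambda
estimates the false selection rate:

    RE:  alpha_hat_{RE,P}(lam) = Ibar*_P(lam) / (1 + Sbar_P(lam))
    ER:  alpha_hat_{ER,P}(lam) = Ibar*_P(lam) / (1 + S(lam))

where Ibar*_P and Sbar_P are across-augmentation means of the selected
pseudo-variable count and total selected count, and S(lam) comes from the
original (non-augmented) path.  The critical threshold lambda* is the
smallest lambda whose estimated curve drops below a cut-off c that depends
on the unknown number of irrelevant covariates k_I:

    RE:  c = k_P*alpha0 / (k_P*alpha0 + k_I)        ER:  c = k_P*alpha0 / k_I

k_I is resolved by fixed-point iteration: start from "all candidates
irrelevant", threshold, re-count, repeat until stable.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass

import numpy as np
from joblib import Parallel, delayed

from .data_model import CountMatrix, DesignSpec, log_cpm, upper_quartile_libsize
from .pseudo import MECHANISMS, make_pseudo
from .relevance import SelectionPath, _backward_path_from_logcpm, select_at
from .voom import LowessSmoother, mean_log_count

__all__ = [
    "PseudoPath",
    "FSRResult",
    "pseudo_paths",
    "alpha_re_hat",
    "alpha_er_hat",
    "re_threshold",
    "alpha_curve",
    "estimate_kI_lambda",
    "fsr_select",
    "fsr_from_paths",
]

ESTIMATORS = ("RE", "ER")


@dataclass
class PseudoPath:
    """A backward path over real candidates plus one pseudo-variable set."""

    path: SelectionPath
    pseudo_names: frozenset[str]

    def counts_at(self, lam: float) -> tuple[int, int]:
        """(number of selected pseudo-variables, total selected) at lam."""
        sel = select_at(self.path, lam)
        i_star = sum(1 for name in sel if name in self.pseudo_names)
        return i_star, len(sel)


@dataclass
class FSRResult:
    lambda_grid: np.ndarray
    Ibar_star: np.ndarray
    Sbar_P: np.ndarray
    alpha_hat: np.ndarray
    k_I_hat: int
    lambda_star_hat: float
    selected: tuple[str, ...]
    mechanism: str
    estimator: str
    B: int
    k_p: int
    alpha0: float
    original_path: SelectionPath | None = None

    def to_dict(self) -> dict:
        return {
            "mechanism": self.mechanism,
            "estimator": self.estimator,
            "alpha0": self.alpha0,
            "k_p": self.k_p,
            "B": self.B,
            "k_I_hat": self.k_I_hat,
            "lambda_star_hat": self.lambda_star_hat,
            "selected": list(self.selected),
            "lambda_grid": self.lambda_grid.tolist(),
            "alpha_hat": self.alpha_hat.tolist(),
        }

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2)


def _pseudo_names(k_p: int) -> list[str]:
    return [f"_pseudo_{j + 1}" for j in range(k_p)]


def pseudo_paths(
    cm: CountMatrix,
    spec: DesignSpec,
    mechanism: str,
    k_p: int,
    B: int,
    rng: np.random.Generator,
    n_jobs: int = 1,
) -> list[PseudoPath]:
    """Run B pseudo-augmented backward paths.

    Each augmentation b draws its own pseudo-variable set from a child seed
    of ``rng``, so results do not depend on execution order or parallelism.
    """
    if cm.libsize is None:
        cm = cm.with_libsize(upper_quartile_libsize(cm))
    y = log_cpm(cm).y
    names = _pseudo_names(k_p)
    seeds = rng.integers(0, 2**31 - 1, size=B)
    smoother = LowessSmoother(mean_log_count(y, cm.libsize)) if y.shape[0] >= 10 else None

    def one(seed: int) -> PseudoPath:
        b_rng = np.random.default_rng(seed)
        ps = make_pseudo(mechanism, spec, k_p, b_rng)
        aug = spec.augmented(ps.Z, names)
        path = _backward_path_from_logcpm(y, cm.libsize, aug, smoother=smoother)
        return PseudoPath(path=path, pseudo_names=frozenset(names))

    if n_jobs == 1:
        return [one(int(s)) for s in seeds]
    return Parallel(n_jobs=n_jobs)(delayed(one)(int(s)) for s in seeds)


def _mean_counts(paths: list[PseudoPath], lam: float) -> tuple[float, float]:
    pairs = [p.counts_at(lam) for p in paths]
    i_bar = float(np.mean([i for i, _ in pairs]))
    s_bar = float(np.mean([s for _, s in pairs]))
    return i_bar, s_bar


def alpha_re_hat(paths: list[PseudoPath], lam: float) -> float:
    """Ibar*_P(lam) / (1 + Sbar_P(lam))."""
    i_bar, s_bar = _mean_counts(paths, lam)
    return i_bar / (1.0 + s_bar)


def alpha_er_hat(paths: list[PseudoPath], original_path: SelectionPath, lam: float) -> float:
    """Ibar*_P(lam) / (1 + S(lam)) with S from the non-augmented path."""
    i_bar, _ = _mean_counts(paths, lam)
    return i_bar / (1.0 + len(select_at(original_path, lam)))


def re_threshold(alpha0: float, k_p: int, k_i: int, estimator: str = "RE") -> float:
    """Cut-off c applied to the estimated pseudo-FSR curve."""
    if k_i < 1:
        raise ValueError("k_i must be at least 1")
    if estimator == "RE":
        return k_p * alpha0 / (k_p * alpha0 + k_i)
    if estimator == "ER":
        return k_p * alpha0 / k_i
    raise ValueError(f"unknown estimator {estimator!r}")


def _lambda_grid(original_path: SelectionPath, paths: list[PseudoPath]) -> np.ndarray:
    vals = {0.0}
    vals.update(r for _, r in original_path.removals)
    for p in paths:
        vals.update(r for _, r in p.path.removals)
    return np.array(sorted(vals))


def _path_counts_on_grid(
    path: SelectionPath, grid: np.ndarray, pseudo_names: frozenset[str] = frozenset()
) -> tuple[np.ndarray, np.ndarray]:
    """(pseudo count, total count) of select_at(path, lam) for every grid lam.

    Vectorizes the stop-at-first-qualifying-removal rule: for each lam the
    selected set is the removal-sequence suffix starting at the first
    recorded r >= lam.
    """
    r = np.array([v for _, v in path.removals])
    m = r.size
    if m == 0:
        z = np.zeros(len(grid))
        return z, z.copy()
    is_pseudo = np.array([name in pseudo_names for name, _ in path.removals])
    # suffix counts: number of (pseudo) removals from index i onward
    suff_total = np.arange(m, 0, -1)
    suff_pseudo = np.cumsum(is_pseudo[::-1])[::-1]
    qualifies = r[None, :] >= grid[:, None]          # grid × removals
    any_q = qualifies.any(axis=1)
    first = np.argmax(qualifies, axis=1)
    total = np.where(any_q, suff_total[first], 0)
    pseudo = np.where(any_q, suff_pseudo[first], 0)
    return pseudo.astype(float), total.astype(float)


def alpha_curve(
    paths: list[PseudoPath],
    original_path: SelectionPath,
    grid: np.ndarray,
    estimator: str,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """alpha_hat over the grid plus the Ibar*_P and Sbar_P step curves."""
    grid = np.asarray(grid, dtype=float)
    i_bar = np.zeros(len(grid))
    s_bar = np.zeros(len(grid))
    for p in paths:
        pse, tot = _path_counts_on_grid(p.path, grid, p.pseudo_names)
        i_bar += pse
        s_bar += tot
    i_bar /= len(paths)
    s_bar /= len(paths)
    _, s_orig = _path_counts_on_grid(original_path, grid)
    if estimator == "RE":
        alpha = i_bar / (1.0 + s_bar)
    elif estimator == "ER":
        alpha = i_bar / (1.0 + s_orig)
    else:
        raise ValueError(f"unknown estimator {estimator!r}")
    return alpha, i_bar, s_bar


def estimate_kI_lambda(
    alpha_hat: np.ndarray,
    grid: np.ndarray,
    original_path: SelectionPath,
    alpha0: float,
    k_p: int,
    estimator: str,
) -> tuple[int, float]:
    """Fixed-point estimation of (k_I, lambda*).

    Initialize k_I at the number of candidates (all irrelevant); then
    repeatedly threshold the curve at c(alpha0, k_P, k_I), take the
    smallest qualifying grid point as lambda*, and re-count k_I as the
    number of unselected candidates (floored at 1), until the count is
    stable or the iteration cap is reached.
    """
    k_c = len(original_path.candidates)
    if k_c == 0:
        return 0, 0.0
    k_i = k_c
    lam_star = math.inf
    for _ in range(k_c):
        c = re_threshold(alpha0, k_p, k_i, estimator)
        ok = grid[alpha_hat <= c]
        lam_star = float(ok[0]) if ok.size else math.inf
        selected = select_at(original_path, lam_star) if math.isfinite(lam_star) else ()
        new_k_i = max(k_c - len(selected), 1)
        if new_k_i == k_i:
            break
        k_i = new_k_i
    return k_i, lam_star


def fsr_from_paths(
    original_path: SelectionPath,
    paths: list[PseudoPath],
    alpha0: float,
    k_p: int,
    estimator: str,
    mechanism: str = "",
) -> FSRResult:
    """Assemble an FSRResult from precomputed paths (shared across variants)."""
    grid = _lambda_grid(original_path, paths)
    alpha, i_bar, s_bar = alpha_curve(paths, original_path, grid, estimator)
    k_i, lam_star = estimate_kI_lambda(
        alpha, grid, original_path, alpha0, k_p, estimator
    )
    selected = (
        select_at(original_path, lam_star) if math.isfinite(lam_star) else ()
    )
    return FSRResult(
        lambda_grid=grid,
        Ibar_star=i_bar,
        Sbar_P=s_bar,
        alpha_hat=alpha,
        k_I_hat=k_i,
        lambda_star_hat=lam_star,
        selected=selected,
        mechanism=mechanism,
        estimator=estimator,
        B=len(paths),
        k_p=k_p,
        alpha0=alpha0,
        original_path=original_path,
    )


def fsr_select(
    cm: CountMatrix,
    spec: DesignSpec,
    alpha0: float = 0.05,
    k_p: int = 7,
    B: int = 100,
    mechanism: str = "ORX",
    estimator: str = "RE",
    rng: np.random.Generator | None = None,
    n_jobs: int = 1,
) -> FSRResult:
    """Full pseudo-variable-augmented covariate selection.

    Steps: backward elimination on the original data; B pseudo-augmented
    backward paths; fixed-point estimation of (k_I, lambda*); selection of
    the final covariate set from the original path at lambda*.
    """
    if mechanism not in MECHANISMS:
        raise ValueError(f"unknown mechanism {mechanism!r}")
    if estimator not in ESTIMATORS:
        raise ValueError(f"unknown estimator {estimator!r}")
    if rng is None:
        rng = np.random.default_rng()
    if cm.libsize is None:
        cm = cm.with_libsize(upper_quartile_libsize(cm))
    if not spec.candidate_names:
        return FSRResult(
            lambda_grid=np.array([0.0]),
            Ibar_star=np.array([0.0]),
            Sbar_P=np.array([0.0]),
            alpha_hat=np.array([0.0]),
            k_I_hat=0,
            lambda_star_hat=0.0,
            selected=(),
            mechanism=mechanism,
            estimator=estimator,
            B=B,
            k_p=k_p,
            alpha0=alpha0,
        )
    y = log_cpm(cm).y
    original = _backward_path_from_logcpm(y, cm.libsize, spec)
    paths = pseudo_paths(cm, spec, mechanism, k_p, B, rng, n_jobs=n_jobs)
    return fsr_from_paths(original, paths, alpha0, k_p, estimator, mechanism)
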