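"""Covariate relevance measure and backward elimination.

A candidate covariate's relevance is judged from its vector of per-gene
p-values: r = #(p <= 0.05) / max(#(p >= 0.75) / 5, 1).  Under a uniform
(irrelevant) p-value distribution both the numerator and the scaled
denominator estimate 0.05*G, so r is close to 1; an excess of small
p-values drives r far above 1.  Backward elimination repeatedly removes
the least relevant candidate and refits the voom model until no
candidates remain, recording (covariate, r) at every removal.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .data_model import CountMatrix, DesignSpec, build_design, log_cpm, upper_quartile_libsize
import math

from scipy import special

from .voom import (
    LowessSmoother,
    ModeratedTests,
    VoomFit,
    mean_log_count,
    moderated_f,
    moderated_t,
    test_variable,
    voom_pipeline,
)

__all__ = ["relevance", "SelectionPath", "backward_path", "select_at", "candidate_pvalues"]


def relevance(p: np.ndarray) -> float:
    """r = #(p <= 0.05) / max(#(p >= 0.75)/5, 1); both comparisons inclusive."""
    p = np.asarray(p, dtype=float)
    if p.size == 0:
        raise ValueError("empty p-value vector")
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    num = float(np.count_nonzero(p <= 0.05))
    den = max(np.count_nonzero(p >= 0.75) / 5.0, 1.0)
    return num / den


@dataclass
class SelectionPath:
    """Ordered record of backward-elimination removals.

    ``removals`` is a permutation of ``candidates`` (the path is run to
    exhaustion) with the relevance value recorded at each removal.
    """

    removals: list[tuple[str, float]]
    candidates: tuple[str, ...]
    primary: tuple[str, ...]

    def __post_init__(self) -> None:
        if sorted(n for n, _ in self.removals) != sorted(self.candidates):
            raise ValueError("removals must be a permutation of the candidates")
        if any(r < 0 for _, r in self.removals):
            raise ValueError("relevance values must be non-negative")


def candidate_pvalues(
    fit: VoomFit,
    tests: ModeratedTests,
    blocks: dict[str, np.ndarray],
    candidates: tuple[str, ...],
) -> dict[str, np.ndarray]:
    """Per-gene p-value vector for each candidate's coefficient block."""
    return {name: test_variable(fit, tests, blocks[name]) for name in candidates}


def backward_path(cm: CountMatrix, spec: DesignSpec) -> SelectionPath:
    """Backward elimination over the candidate covariates.

    Each iteration fits voom + moderated tests on the current model,
    computes r for every remaining candidate, and removes the one with the
    smallest r (ties broken by declaration order).  The voom weights are
    recomputed for every reduced model.
    """
    if cm.libsize is None:
        cm = cm.with_libsize(upper_quartile_libsize(cm))
    y = log_cpm(cm).y
    return _backward_path_from_logcpm(y, cm.libsize, spec)


def _relevance_all(
    fit: VoomFit,
    tests: ModeratedTests,
    blocks: dict[str, np.ndarray],
    names: list[str],
) -> dict[str, float]:
    """r for every named block, via critical values of the moderated null.

    Counting #(p <= 0.05) is equivalent to counting |t| (or F) beyond the
    matching quantile of the reference distribution, which avoids
    materializing the full p-value matrix in the hot selection loop.
    """
    df = tests.df_total
    rvals: dict[str, float] = {}
    singles = [nm for nm in names if len(blocks[nm]) == 1]
    if singles:
        cols = np.array([blocks[nm][0] for nm in singles])
        abs_t = np.abs(moderated_t(fit, tests, cols))
        if math.isinf(df):
            c_small, c_large = special.ndtri(0.975), special.ndtri(0.625)
        else:
            c_small, c_large = special.stdtrit(df, 0.975), special.stdtrit(df, 0.625)
        num = (abs_t >= c_small).sum(axis=0)
        den = np.maximum((abs_t <= c_large).sum(axis=0) / 5.0, 1.0)
        for j, nm in enumerate(singles):
            rvals[nm] = float(num[j] / den[j])
    for nm in names:
        if nm in rvals:
            continue
        q = len(blocks[nm])
        F = moderated_f(fit, tests, blocks[nm])
        if math.isinf(df):
            c_small = special.chdtri(q, 0.05) / q
            c_large = special.chdtri(q, 0.75) / q
        else:
            c_small = special.fdtri(q, df, 0.95)
            c_large = special.fdtri(q, df, 0.25)
        num = int((F >= c_small).sum())
        den = max((F <= c_large).sum() / 5.0, 1.0)
        rvals[nm] = float(num / den)
    return rvals


def _backward_path_from_logcpm(
    y: np.ndarray,
    libsize: np.ndarray,
    spec: DesignSpec,
    smoother: LowessSmoother | None = None,
) -> SelectionPath:
    if smoother is None and y.shape[0] >= 10:
        smoother = LowessSmoother(mean_log_count(y, libsize))
    # validate the full design once; reduced models are column slices of it
    X_full, blocks_full = build_design(spec, spec.candidate_names)
    base_cols = [0] + [c for nm in spec.primary_names for c in blocks_full[nm]]
    remaining = list(spec.candidate_names)
    removals: list[tuple[str, float]] = []
    while remaining:
        cols = list(base_cols)
        blocks: dict[str, np.ndarray] = {}
        for nm in remaining:
            width = len(blocks_full[nm])
            blocks[nm] = np.arange(len(cols), len(cols) + width)
            cols.extend(blocks_full[nm])
        X = X_full[:, cols]
        if X.shape[1] >= X.shape[0]:
            raise ValueError(
                "design matrix rank must be smaller than the number of samples"
            )
        fit, tests = voom_pipeline(y, libsize, X, smoother=smoother, check_rank=False)
        rvals = _relevance_all(fit, tests, blocks, remaining)
        worst = min(remaining, key=rvals.__getitem__)  # first minimum wins ties
        removals.append((worst, rvals[worst]))
        remaining.remove(worst)
    return SelectionPath(
        removals=removals,
        candidates=spec.candidate_names,
        primary=spec.primary_names,
    )


def select_at(path: SelectionPath, lam: float) -> tuple[str, ...]:
    """Covariates selected at threshold lam.

    Scan the removal sequence in order and stop at the first removal whose
    recorded r is at least lam; the selected set is that covariate together
    with everything not yet removed.  If no removal qualifies the selected
    set is empty.
    """
    if lam < 0:
        raise ValueError("lam must be non-negative")
    for i, (_, r) in enumerate(path.removals):
        if r >= lam:
            return tuple(name for name, _ in path.removals[i:])
    return ()
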