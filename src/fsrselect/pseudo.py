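"""Pseudo-variable generation: covariates known to be irrelevant by design.

Four mechanisms: WN draws i.i.d. standard-normal columns; RX takes randomly
chosen columns of the candidate design block and applies one shared random
row permutation; OWN and ORX project the WN / RX draws onto the orthogonal
complement of the full design's column space (intercept included), which
forces exact zero sample means and zero sample correlations with every
design column.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .data_model import DesignSpec, build_design

__all__ = [
    "PseudoSet",
    "generate_wn",
    "generate_rx",
    "orthogonalize",
    "make_pseudo",
    "MECHANISMS",
]

MECHANISMS = ("WN", "RX", "OWN", "ORX")


@dataclass
class PseudoSet:
    Z: np.ndarray            # n × k_P
    mechanism: str
    seed: int | None = None

    @property
    def k_p(self) -> int:
        return self.Z.shape[1]


def generate_wn(n: int, k_p: int, rng: np.random.Generator) -> PseudoSet:
    """White-noise pseudo-variables: entries i.i.d. N(0, 1)."""
    if k_p < 1:
        raise ValueError("k_p must be at least 1")
    return PseudoSet(Z=rng.standard_normal((n, k_p)), mechanism="WN")


def generate_rx(pool: np.ndarray, k_p: int, rng: np.random.Generator) -> PseudoSet:
    """Row-permuted real columns: pick k_p columns of the pool without
    replacement and apply one shared random row permutation."""
    pool = np.asarray(pool, dtype=float)
    n, m = pool.shape
    if k_p < 1:
        raise ValueError("k_p must be at least 1")
    if m < k_p:
        raise ValueError(f"column pool has {m} columns but k_p = {k_p}")
    cols = rng.choice(m, size=k_p, replace=False)
    perm = rng.permutation(n)
    return PseudoSet(Z=pool[np.ix_(perm, cols)], mechanism="RX")


def orthogonalize(ps: PseudoSet, X_full: np.ndarray) -> PseudoSet:
    """Replace Z by (I - H) Z with H the projector onto the span of the
    intercept-augmented full design.

    Requires rank(X_full) + k_p <= n - 1 so the augmented model keeps at
    least one residual degree of freedom.
    """
    X_full = np.asarray(X_full, dtype=float)
    n = X_full.shape[0]
    rank = np.linalg.matrix_rank(X_full)
    k_max = n - 1 - rank
    if ps.k_p > k_max:
        raise ValueError(
            f"k_p = {ps.k_p} leaves no residual degrees of freedom; "
            f"at most {k_max} pseudo-variables are admissible"
        )
    Q, _ = np.linalg.qr(X_full)
    Z = ps.Z - Q @ (Q.T @ ps.Z)
    mech = "O" + ps.mechanism if not ps.mechanism.startswith("O") else ps.mechanism
    return PseudoSet(Z=Z, mechanism=mech, seed=ps.seed)


def make_pseudo(
    mechanism: str, spec: DesignSpec, k_p: int, rng: np.random.Generator
) -> PseudoSet:
    """Dispatch on mechanism name.

    The RX column pool is the expanded design block of the candidate
    covariates only (primary variables are excluded so permuted copies of
    the primary signal are never injected).  Orthogonalization projects
    against the full design: intercept, primaries, and all candidates.
    """
    if mechanism not in MECHANISMS:
        raise ValueError(f"unknown mechanism {mechanism!r}; choose from {MECHANISMS}")
    n = spec.n_samples
    base = mechanism.removeprefix("O")
    if base == "WN":
        ps = generate_wn(n, k_p, rng)
    else:
        X, blocks = build_design(spec, spec.candidate_names)
        cand_cols = np.concatenate(
            [blocks[name] for name in spec.candidate_names]
        ) if spec.candidate_names else np.array([], dtype=int)
        if cand_cols.size == 0:
            raise ValueError("RX needs at least one candidate covariate column")
        ps = generate_rx(X[:, cand_cols], k_p, rng)
    if mechanism.startswith("O"):
        X_full, _ = build_design(spec, spec.candidate_names)
        ps = orthogonalize(ps, X_full)
    ps.mechanism = mechanism
    return ps
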