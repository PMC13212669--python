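"""Storey q-values with a histogram estimator of the true-null proportion.

The true-null proportion pi0 is estimated from the p-value histogram: with
20 equal-width right-closed bins, walk from the left and find the first bin
whose count does not exceed the mean count of the remaining bins; pooling
that tail gives the estimated number of uniform (null) p-values.  q-values
are the Storey step-up quantities q_(i) = min_{j>=i} pi0 * G * p_(j) / j.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "QValueResult",
    "estimate_pi0_histogram",
    "qvalues",
    "declare_de",
    "de_table",
]


@dataclass
class QValueResult:
    pi0: float
    qvals: np.ndarray
    n_true_null_hat: float


def estimate_pi0_histogram(p: np.ndarray, n_bins: int = 20) -> float:
    """Histogram-based estimate of the proportion of true null hypotheses."""
    p = np.asarray(p, dtype=float)
    if p.size == 0:
        raise ValueError("empty p-value vector")
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    G = p.size
    # right-closed bins ((j-1)/B, j/B]; p = 0 falls in the first bin
    idx = np.ceil(p * n_bins).astype(int)
    idx = np.clip(idx, 1, n_bins)
    counts = np.bincount(idx, minlength=n_bins + 1)[1:]
    tail_means = counts[::-1].cumsum()[::-1] / np.arange(n_bins, 0, -1)
    i = int(np.nonzero(counts <= tail_means)[0][0])  # 0-based; always exists
    pi0 = counts[i:].sum() / (G * (n_bins - i) / n_bins)
    return float(min(max(pi0, 1.0 / G), 1.0))


def qvalues(p: np.ndarray, pi0: float) -> QValueResult:
    """Storey q-values: q_(i) = min_{j >= i} pi0 * G * p_(j) / j, capped at 1."""
    p = np.asarray(p, dtype=float)
    if not 0 < pi0 <= 1:
        raise ValueError("pi0 must be in (0, 1]")
    G = p.size
    order = np.argsort(p, kind="stable")
    ranked = pi0 * G * p[order] / np.arange(1, G + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q_sorted = np.minimum(q_sorted, 1.0)
    q = np.empty(G)
    q[order] = q_sorted
    return QValueResult(pi0=float(pi0), qvals=q, n_true_null_hat=float(pi0 * G))


def declare_de(q: QValueResult, level: float) -> np.ndarray:
    """Genes declared differentially expressed: q-value <= level (inclusive)."""
    if not 0 < level < 1:
        raise ValueError("level must be in (0, 1)")
    return q.qvals <= level


def de_table(gene_ids, pvals: np.ndarray, q: QValueResult, level: float = 0.05):
    """Per-gene results table: gene id, p, q, DE flag (TSV-ready DataFrame)."""
    import pandas as pd

    return pd.DataFrame(
        {
            "gene": list(gene_ids),
            "p": np.asarray(pvals, dtype=float),
            "q": q.qvals,
            "de": declare_de(q, level).astype(int),
        }
    )
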