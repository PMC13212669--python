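"""Scoring of covariate selection and differential-expression calls against
simulation truth, plus the multi-strategy comparison harness.

Selection is scored with the per-replicate false selection rate I/(1+S)
and the count of selected truly relevant covariates; DE calls with the
empirical FDR, the number of true positives at a q-value cut-off, and the
standardized partial AUC at false positive rate <= 0.05.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from sklearn.metrics import roc_curve

from .data_model import build_design, log_cpm, upper_quartile_libsize
from .fsr import fsr_from_paths, pseudo_paths
from .multiple_testing import declare_de, estimate_pi0_histogram, qvalues
from .relevance import _backward_path_from_logcpm
from .simulate import SimConfig, build_scenario, simulate_counts
from .voom import test_variable, voom_pipeline

__all__ = ["eval_selection", "eval_de", "partial_auc", "StudyConfig", "run_study", "de_analysis"]


def eval_selection(
    selected: Iterable[str], relevant_truth: Iterable[str]
) -> tuple[float, int]:
    """Per-replicate (false selection rate I/(1+S), truly-relevant count)."""
    selected = set(selected)
    truth = set(relevant_truth)
    n_irrelevant = len(selected - truth)
    return n_irrelevant / (1.0 + len(selected)), len(selected & truth)


def eval_de(
    qvals: np.ndarray, de_truth: np.ndarray, level: float = 0.05
) -> tuple[float, int]:
    """(empirical FDR, number of true positives) at q <= level."""
    if not 0 < level < 1:
        raise ValueError("level must be in (0, 1)")
    qvals = np.asarray(qvals, dtype=float)
    de_truth = np.asarray(de_truth, dtype=bool)
    disc = qvals <= level
    false = int(np.count_nonzero(disc & ~de_truth))
    ntp = int(np.count_nonzero(disc & de_truth))
    return false / max(1, int(disc.sum())), ntp


def partial_auc(
    scores: np.ndarray, de_truth: np.ndarray, fpr_max: float = 0.05
) -> float:
    """Standardized partial AUC over FPR in [0, fpr_max].

    ``scores`` are p-values (smaller = more evidence of DE).  The ROC area
    up to fpr_max is divided by fpr_max, so 1.0 is perfect separation and
    a random ranking scores fpr_max/2 (0.025 at the default cut-off).
    """
    de_truth = np.asarray(de_truth, dtype=bool)
    if de_truth.all() or not de_truth.any():
        raise ValueError("need both DE and EE genes to compute a ROC curve")
    fpr, tpr, _ = roc_curve(de_truth, -np.asarray(scores, dtype=float))
    tpr_at_max = np.interp(fpr_max, fpr, tpr)
    keep = fpr < fpr_max
    xs = np.concatenate([fpr[keep], [fpr_max]])
    ys = np.concatenate([tpr[keep], [tpr_at_max]])
    return float(np.trapezoid(ys, xs) / fpr_max)


def de_analysis(
    y: np.ndarray,
    libsize: np.ndarray,
    spec,
    covariates: Sequence[str],
    level: float = 0.05,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """voom + moderated test of the primary variable given chosen covariates.

    Returns (p-values, q-values, DE flags) for the first primary variable.
    """
    X, blocks = build_design(spec, covariates)
    fit, tests = voom_pipeline(y, libsize, X)
    pvals = test_variable(fit, tests, blocks[spec.primary_names[0]])
    qr = qvalues(pvals, estimate_pi0_histogram(pvals))
    return pvals, qr.qvals, declare_de(qr, level)


@dataclass
class StudyConfig:
    """Configuration of the multi-strategy simulation comparison."""

    scenarios: list[SimConfig]
    n_reps: int = 100
    alpha0: float = 0.05
    k_p: int = 7
    B: int = 100
    mechanisms: tuple[str, ...] = ("WN", "RX", "OWN", "ORX")
    estimators: tuple[str, ...] = ("RE", "ER")
    include_baselines: bool = True   # Full, LineOnly, Oracle
    de_level: float = 0.05
    seed: int = 0


def _summarize(rows: list[dict]) -> pd.DataFrame:
    """Tidy long table: scenario, strategy, metric, mean, se (SD/sqrt(reps))."""
    df = pd.DataFrame(rows)
    long = df.melt(
        id_vars=["scenario", "strategy", "rep"], var_name="metric", value_name="value"
    )
    out = (
        long.groupby(["scenario", "strategy", "metric"])["value"]
        .agg(mean="mean", se=lambda v: v.std(ddof=1) / np.sqrt(len(v)))
        .reset_index()
    )
    return out


def run_study(config: StudyConfig, keep_reps: bool = False):
    """Run the strategy comparison: each FSR variant plus Full / LineOnly /
    Oracle baselines, scored per replicate and aggregated with Monte-Carlo
    standard errors.

    Pseudo-augmented paths are computed once per mechanism and shared
    between the RE and ER estimators.
    """
    master = np.random.default_rng(config.seed)
    rows: list[dict] = []
    for s_idx, scen_cfg in enumerate(config.scenarios):
        for rep in range(config.n_reps):
            rng = np.random.default_rng(master.integers(0, 2**31 - 1))
            sc = build_scenario(scen_cfg, rng)
            cm = simulate_counts(sc, rng)
            cm = cm.with_libsize(upper_quartile_libsize(cm))
            y = log_cpm(cm).y
            spec = sc.design
            original = _backward_path_from_logcpm(y, cm.libsize, spec)
            strategies: dict[str, tuple[str, ...]] = {}
            for mech in config.mechanisms:
                paths = pseudo_paths(
                    cm, spec, mech, config.k_p, config.B, rng
                )
                for est in config.estimators:
                    res = fsr_from_paths(
                        original, paths, config.alpha0, config.k_p, est, mech
                    )
                    strategies[f"{mech}_{est}"] = res.selected
            if config.include_baselines:
                strategies["Full"] = spec.candidate_names
                strategies["LineOnly"] = ()
                strategies["Oracle"] = sc.relevant_set
            for name, selected in strategies.items():
                fsr_rep, s_count = eval_selection(selected, sc.relevant_set)
                pvals, qv, _ = de_analysis(
                    y, cm.libsize, spec, selected, config.de_level
                )
                fdr, ntp = eval_de(qv, sc.de_truth, config.de_level)
                pauc = partial_auc(pvals, sc.de_truth)
                rows.append(
                    {
                        "scenario": f"kR{scen_cfg.k_relevant}_{s_idx}",
                        "strategy": name,
                        "rep": rep,
                        "fsr": fsr_rep,
                        "s_count": s_count,
                        "fdr": fdr,
                        "ntp": ntp,
                        "pauc": pauc,
                    }
                )
    summary = _summarize(rows)
    if keep_reps:
        return summary, pd.DataFrame(rows)
    return summary
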