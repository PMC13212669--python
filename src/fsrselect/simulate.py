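"""Synthetic RNA-seq count generator: inverse of the voom analysis model.

Each gene follows a Gaussian linear model on the log-CPM scale,

    y_gi = x_i' beta_g + eps_gi,   eps_gi ~ N(0, sigma_g^2 / w_gi),

with per-gene error variances drawn from a scaled inverse-chi-squared
prior, precision weights taken from a decreasing quarter-root
standard-deviation trend in expected log-count (the mean-variance shape
voom models), and counts recovered by inverting the log-CPM transform:
c_gi = round(2^{y_gi} (R_i + 1) / 1e6 - 0.5), clamped at 0.

A designated subset of candidate covariates is relevant (nonzero
coefficients on a fraction of genes, standardized by the gene's error
standard deviation); all coefficients of irrelevant covariates are zero.
A configurable fraction of genes has a zero primary-variable coefficient
block (EE genes); the rest are DE.  Optionally one relevant covariate is
generated to be correlated with the primary variable, reproducing the
confounded regime where ignoring the covariate breaks FDR control.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .data_model import (
    LOG2_MILLION,
    CountMatrix,
    DesignSpec,
    Variable,
    build_design,
    counts_from_logcpm,
)

__all__ = ["SimConfig", "SimScenario", "build_scenario", "simulate_counts", "make_confounded_covariate"]


@dataclass
class SimConfig:
    """Study conditions for one synthetic scenario.

    Defaults describe a typical bulk RNA-seq study: G = 2000 genes,
    n = 31 samples, a binary primary variable, 13 candidate covariates of
    which ``k_relevant`` carry signal, an 80/20 EE/DE split on the primary
    variable, and standardized N(0, 1) effect sizes.
    """

    n_genes: int = 2000
    n_samples: int = 31
    n_candidates: int = 13
    k_relevant: int = 2
    ee_fraction: float = 0.8
    affected_fraction: float = 0.3   # genes with nonzero coefficient per relevant covariate
    effect_sd: float = 1.0           # covariate effects: N(0, effect_sd^2) * sigma_g
    primary_effect_sd: float = 1.0   # DE effects: N(0, primary_effect_sd^2) * sigma_g
    confounded_corr: float | None = None  # correlate the last relevant covariate with the primary
    prior_d0: float = 4.0            # sigma_g^2 ~ s0sq * d0 / chi2_{d0}
    prior_s0sq: float = 0.25
    intercept_mean: float = 5.0
    intercept_sd: float = 1.5
    libsize_log_mean: float = math.log(5e5)
    libsize_log_sd: float = 0.2
    categorical_levels: tuple[int, ...] = ()  # extra categorical candidates


@dataclass
class SimScenario:
    design: DesignSpec
    X: np.ndarray                # expanded design, intercept first
    blocks: dict[str, np.ndarray]
    beta: np.ndarray             # G × p true coefficients
    sigma2: np.ndarray           # per-gene error variances
    weights: np.ndarray          # G × n precision truth
    libsize: np.ndarray
    relevant_set: tuple[str, ...]
    de_truth: np.ndarray         # per-gene bool

    def __post_init__(self) -> None:
        if np.any(self.sigma2 <= 0) or np.any(self.weights <= 0):
            raise ValueError("sigma2 and weights must be strictly positive")

    @property
    def mu(self) -> np.ndarray:
        """Expected log-CPM values x_i' beta_g."""
        return self.beta @ self.X.T


def make_confounded_covariate(
    primary: np.ndarray, target_corr: float, rng: np.random.Generator
) -> np.ndarray:
    """A covariate with the requested population correlation to the primary
    variable: scaled standardized primary plus Gaussian noise."""
    if not abs(target_corr) < 1:
        raise ValueError("target correlation must satisfy |rho| < 1")
    primary = np.asarray(primary, dtype=float)
    sd = primary.std()
    if sd == 0:
        raise ValueError("primary variable is constant")
    z = (primary - primary.mean()) / sd
    return target_corr * z + math.sqrt(1.0 - target_corr**2) * rng.standard_normal(
        primary.size
    )


def _quarter_sd_trend(logcount: np.ndarray) -> np.ndarray:
    # decreasing sqrt-sd vs abundance, the shape voom's LOWESS trend captures
    return np.clip(1.25 - 0.05 * logcount, 0.6, 1.2)


def build_scenario(config: SimConfig, rng: np.random.Generator) -> SimScenario:
    """Draw covariate values, true coefficients, variances, and weights."""
    G, n = config.n_genes, config.n_samples
    k_c = config.n_candidates + len(config.categorical_levels)
    if config.k_relevant > k_c:
        raise ValueError(
            f"k_relevant = {config.k_relevant} exceeds the {k_c} candidates"
        )
    primary = (np.arange(n) >= n // 2).astype(float)  # balanced two-group design
    data = {"group": primary}
    cont_names = [f"cov{j + 1:02d}" for j in range(config.n_candidates)]
    relevant = tuple(cont_names[: min(config.k_relevant, config.n_candidates)])
    for name in cont_names:
        data[name] = rng.standard_normal(n)
    if config.confounded_corr is not None and relevant:
        data[relevant[-1]] = make_confounded_covariate(
            primary, config.confounded_corr, rng
        )
    variables = [Variable("group", "continuous", "primary")] + [
        Variable(name, "continuous", "candidate") for name in cont_names
    ]
    for j, n_levels in enumerate(config.categorical_levels):
        name = f"fct{j + 1}"
        levels = tuple(chr(ord("a") + m) for m in range(n_levels))
        data[name] = [levels[i % n_levels] for i in range(n)]
        variables.append(Variable(name, "categorical", "candidate", levels))
        if len(relevant) < config.k_relevant:
            relevant = relevant + (name,)
    df = pd.DataFrame(data, index=[f"s{i + 1:02d}" for i in range(n)])
    spec = DesignSpec(variables=variables, data=df)
    X, blocks = build_design(spec, spec.candidate_names)

    sigma2 = (
        config.prior_s0sq * config.prior_d0 / rng.chisquare(config.prior_d0, size=G)
        if math.isfinite(config.prior_d0)
        else np.full(G, config.prior_s0sq)
    )
    sigma = np.sqrt(sigma2)

    beta = np.zeros((G, X.shape[1]))
    beta[:, 0] = rng.normal(config.intercept_mean, config.intercept_sd, size=G)
    n_de = G - int(round(config.ee_fraction * G))
    de_truth = np.zeros(G, dtype=bool)
    de_idx = rng.permutation(G)[:n_de]
    de_truth[de_idx] = True
    for col in blocks["group"]:
        beta[de_idx, col] = rng.normal(0.0, config.primary_effect_sd, size=n_de) * sigma[de_idx]
    for name in relevant:
        hit = rng.random(G) < config.affected_fraction
        idx = np.nonzero(hit)[0]
        for col in blocks[name]:
            beta[idx, col] = rng.normal(0.0, config.effect_sd, size=idx.size) * sigma[idx]

    libsize = rng.lognormal(config.libsize_log_mean, config.libsize_log_sd, size=n)
    mu = beta @ X.T
    logcount = mu + (np.log2(libsize + 1.0) - LOG2_MILLION)[None, :]
    weights = _quarter_sd_trend(logcount) ** -4.0
    # a gene counts as DE/relevant only if its block is actually nonzero
    de_truth = np.any(beta[:, blocks["group"]] != 0, axis=1)
    relevant = tuple(
        name for name in relevant if np.any(beta[:, blocks[name]] != 0)
    )
    return SimScenario(
        design=spec,
        X=X,
        blocks=blocks,
        beta=beta,
        sigma2=sigma2,
        weights=weights,
        libsize=libsize,
        relevant_set=relevant,
        de_truth=de_truth,
    )


def simulate_counts(sc: SimScenario, rng: np.random.Generator) -> CountMatrix:
    """Draw y from the per-gene weighted Gaussian model and invert to counts."""
    G, n = sc.beta.shape[0], sc.X.shape[0]
    noise_sd = np.sqrt(sc.sigma2[:, None] / sc.weights)
    y = sc.mu + rng.standard_normal((G, n)) * noise_sd
    counts = counts_from_logcpm(y, sc.libsize)
    return CountMatrix(
        counts=counts,
        gene_ids=tuple(f"g{g + 1:05d}" for g in range(G)),
        sample_ids=tuple(sc.design.data.index),
    )
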