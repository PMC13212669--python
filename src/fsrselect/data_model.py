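"""Count matrices, log-CPM transforms, and design-matrix construction.

The analysis operates on a gene × sample matrix of non-negative integer
read counts together with a sample-level covariate table.  Counts are
normalized to log-counts-per-million using per-sample library sizes
``R_i`` taken as the upper quartile of each sample's counts, and all
per-gene models are linear models on that log-CPM scale.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "CountMatrix",
    "LogCPM",
    "Variable",
    "DesignSpec",
    "load_counts",
    "load_covariates",
    "upper_quartile_libsize",
    "log_cpm",
    "inverse_log_cpm",
    "counts_from_logcpm",
    "filter_genes",
    "build_design",
]

LOG2_MILLION = np.log2(1e6)


class ValidationError(ValueError):
    """Raised when an input table violates a structural contract."""


def _check_unique(ids: Sequence[str], what: str) -> None:
    seen: dict[str, int] = {}
    for i, x in enumerate(ids):
        if x in seen:
            raise ValidationError(f"duplicate {what} {x!r} (positions {seen[x]} and {i})")
        seen[x] = i


@dataclass
class CountMatrix:
    """Gene × sample read counts with optional per-sample library sizes."""

    counts: np.ndarray
    gene_ids: tuple[str, ...]
    sample_ids: tuple[str, ...]
    libsize: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        if self.counts.ndim != 2:
            raise ValidationError("counts must be a 2-d gene × sample array")
        g, n = self.counts.shape
        if len(self.gene_ids) != g or len(self.sample_ids) != n:
            raise ValidationError("id lengths do not match the counts shape")
        self.gene_ids = tuple(str(x) for x in self.gene_ids)
        self.sample_ids = tuple(str(x) for x in self.sample_ids)
        _check_unique(self.gene_ids, "gene id")
        _check_unique(self.sample_ids, "sample id")
        if not np.issubdtype(self.counts.dtype, np.integer):
            frac, _ = np.modf(self.counts)
            if np.any(frac != 0):
                gi, si = np.argwhere(frac != 0)[0]
                raise ValidationError(
                    f"non-integer count at gene {self.gene_ids[gi]!r}, "
                    f"sample {self.sample_ids[si]!r}"
                )
            self.counts = self.counts.astype(np.int64)
        if np.any(self.counts < 0):
            gi, si = np.argwhere(self.counts < 0)[0]
            raise ValidationError(
                f"negative count at gene {self.gene_ids[gi]!r}, "
                f"sample {self.sample_ids[si]!r}"
            )
        if self.libsize is not None:
            self.libsize = np.asarray(self.libsize, dtype=float)
            if self.libsize.shape != (n,):
                raise ValidationError("libsize must have one entry per sample")
            if np.any(self.libsize <= 0):
                raise ValidationError("library sizes must be strictly positive")

    @property
    def n_genes(self) -> int:
        return self.counts.shape[0]

    @property
    def n_samples(self) -> int:
        return self.counts.shape[1]

    def with_libsize(self, libsize: np.ndarray) -> "CountMatrix":
        return replace(self, libsize=np.asarray(libsize, dtype=float))


@dataclass
class LogCPM:
    """Log2 counts-per-million values with the per-sample offsets used."""

    y: np.ndarray
    offsets: np.ndarray  # log2(R_i + 1) - log2(1e6)

    def __post_init__(self) -> None:
        self.y = np.asarray(self.y, dtype=float)
        self.offsets = np.asarray(self.offsets, dtype=float)
        if not np.all(np.isfinite(self.y)):
            raise ValidationError("log-CPM values must be finite")


def load_counts(path: str | Path, format: str | None = None) -> CountMatrix:
    """Read a counts table (first column gene ids, one column per sample)."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if format is None:
        format = "csv" if path.suffix.lower() == ".csv" else "tsv"
    sep = "," if format == "csv" else "\t"
    df = pd.read_csv(path, sep=sep, index_col=0)
    return CountMatrix(
        counts=df.to_numpy(),
        gene_ids=tuple(map(str, df.index)),
        sample_ids=tuple(map(str, df.columns)),
    )


def load_covariates(path: str | Path, sample_ids: Sequence[str] | None = None) -> pd.DataFrame:
    """Read the sample × variable covariate table (CSV, first column sample id).

    When ``sample_ids`` is given the rows are checked (by id) to match the
    count matrix column order.
    """
    df = pd.read_csv(path, index_col=0)
    df.index = df.index.map(str)
    if sample_ids is not None:
        missing = [s for s in sample_ids if s not in df.index]
        if missing:
            raise ValidationError(f"covariate table is missing samples {missing}")
        df = df.loc[list(sample_ids)]
    return df


def upper_quartile_libsize(cm: CountMatrix) -> np.ndarray:
    """Per-sample library size: the 75th percentile of the sample's counts.

    Uses linear interpolation of order statistics (the "type 7" quantile
    convention).  An all-zero sample column yields a zero library size and
    is rejected.
    """
    if cm.n_genes < 1:
        raise ValidationError("need at least one gene")
    r = np.percentile(cm.counts, 75, axis=0, method="linear")
    if np.any(r <= 0):
        bad = [cm.sample_ids[i] for i in np.nonzero(r <= 0)[0]]
        raise ValidationError(f"zero upper-quartile library size for samples {bad}")
    return r


def log_cpm(cm: CountMatrix) -> LogCPM:
    """y_gi = log2((c_gi + 0.5) / (R_i + 1) * 1e6)."""
    if cm.libsize is None:
        raise ValidationError("library sizes not computed; call upper_quartile_libsize first")
    offsets = np.log2(cm.libsize + 1.0) - LOG2_MILLION
    y = np.log2(cm.counts + 0.5) - offsets[None, :]
    return LogCPM(y=y, offsets=offsets)


def inverse_log_cpm(lc: LogCPM) -> np.ndarray:
    """Recover the integer counts from log-CPM values (exact after rounding)."""
    c = np.exp2(lc.y + lc.offsets[None, :]) - 0.5
    return np.rint(c).astype(np.int64)


def counts_from_logcpm(y: np.ndarray, libsize: np.ndarray) -> np.ndarray:
    """Map log-CPM-scale values to counts: round(2^y * (R+1)/1e6 - 0.5), clamped at 0."""
    offsets = np.log2(np.asarray(libsize, dtype=float) + 1.0) - LOG2_MILLION
    c = np.exp2(np.asarray(y, dtype=float) + offsets[None, :]) - 0.5
    return np.maximum(np.rint(c), 0).astype(np.int64)


def filter_genes(cm: CountMatrix, min_avg: float, max_zeros: int) -> CountMatrix:
    """Keep genes with mean count >= min_avg and at most max_zeros zero entries."""
    if min_avg < 0 or max_zeros < 0:
        raise ValidationError("thresholds must be non-negative")
    keep = (cm.counts.mean(axis=1) >= min_avg) & (
        (cm.counts == 0).sum(axis=1) <= max_zeros
    )
    if not keep.any():
        raise ValidationError(
            "no genes pass the filter; lower min_avg or raise max_zeros"
        )
    return CountMatrix(
        counts=cm.counts[keep],
        gene_ids=tuple(np.asarray(cm.gene_ids)[keep]),
        sample_ids=cm.sample_ids,
        libsize=cm.libsize,
    )


# ---------------------------------------------------------------------------
# design specification


@dataclass(frozen=True)
class Variable:
    name: str
    kind: str  # "continuous" | "categorical"
    role: str  # "primary" | "candidate"
    levels: tuple[str, ...] | None = None

    def __post_init__(self) -> None:
        if self.kind not in ("continuous", "categorical"):
            raise ValidationError(f"unknown kind {self.kind!r} for variable {self.name!r}")
        if self.role not in ("primary", "candidate"):
            raise ValidationError(f"unknown role {self.role!r} for variable {self.name!r}")


@dataclass
class DesignSpec:
    """Declares primary variables (never removed) and candidate covariates.

    ``data`` holds the observed values, one row per sample in count-matrix
    column order.  Categorical variables are expanded to L-1 treatment
    indicators against the first declared level.
    """

    variables: list[Variable]
    data: pd.DataFrame

    def __post_init__(self) -> None:
        names = [v.name for v in self.variables]
        _check_unique(names, "variable name")
        if not any(v.role == "primary" for v in self.variables):
            raise ValidationError("at least one primary variable is required")
        missing = [n for n in names if n not in self.data.columns]
        if missing:
            raise ValidationError(f"covariate table lacks columns {missing}")
        fixed = []
        for v in self.variables:
            if v.kind == "categorical" and v.levels is None:
                levels = tuple(dict.fromkeys(self.data[v.name].astype(str)))
                v = Variable(v.name, v.kind, v.role, levels)
            fixed.append(v)
        self.variables = fixed

    @property
    def primary_names(self) -> tuple[str, ...]:
        return tuple(v.name for v in self.variables if v.role == "primary")

    @property
    def candidate_names(self) -> tuple[str, ...]:
        return tuple(v.name for v in self.variables if v.role == "candidate")

    def variable(self, name: str) -> Variable:
        for v in self.variables:
            if v.name == name:
                return v
        raise KeyError(name)

    @property
    def n_samples(self) -> int:
        return len(self.data)

    @classmethod
    def from_config(cls, config: Mapping, data: pd.DataFrame) -> "DesignSpec":
        """Build from a config mapping with keys primary[], candidates[], types{}, levels{}."""
        types = config.get("types", {})
        levels = config.get("levels", {})
        variables = []
        for role, key in (("primary", "primary"), ("candidate", "candidates")):
            for name in config.get(key, []):
                variables.append(
                    Variable(
                        name=name,
                        kind=types.get(name, "continuous"),
                        role=role,
                        levels=tuple(levels[name]) if name in levels else None,
                    )
                )
        return cls(variables=variables, data=data)

    def augmented(self, Z: np.ndarray, names: Sequence[str]) -> "DesignSpec":
        """Append continuous candidate columns (used for pseudo-variables)."""
        Z = np.asarray(Z, dtype=float)
        data = self.data.copy()
        for j, name in enumerate(names):
            data[name] = Z[:, j]
        variables = list(self.variables) + [
            Variable(name, "continuous", "candidate") for name in names
        ]
        return DesignSpec(variables=variables, data=data)


def _encode(var: Variable, values: pd.Series) -> np.ndarray:
    if var.kind == "continuous":
        return np.asarray(values, dtype=float)[:, None]
    assert var.levels is not None
    vals = values.astype(str)
    unknown = sorted(set(vals) - set(var.levels))
    if unknown:
        raise ValidationError(f"variable {var.name!r} has undeclared levels {unknown}")
    # treatment contrasts against the first declared level
    return np.column_stack(
        [(vals == lev).to_numpy(dtype=float) for lev in var.levels[1:]]
    )


def build_design(
    spec: DesignSpec, subset: Iterable[str] = ()
) -> tuple[np.ndarray, dict[str, np.ndarray]]:
    """Design matrix for the primaries plus the given candidate subset.

    Columns are intercept, then each primary block, then the blocks of the
    subset candidates in declaration order.  Returns the matrix and a map
    from variable name to its column indices.  The matrix must be full
    column rank; the first block that fails to add its full width raises.
    """
    subset = set(subset)
    extra = subset - set(spec.candidate_names)
    if extra:
        raise ValidationError(f"not candidate covariates: {sorted(extra)}")
    n = spec.n_samples
    cols: list[np.ndarray] = [np.ones((n, 1))]
    blocks: dict[str, np.ndarray] = {}
    pos = 1
    for v in spec.variables:
        if v.role == "candidate" and v.name not in subset:
            continue
        block = _encode(v, spec.data[v.name])
        cols.append(block)
        blocks[v.name] = np.arange(pos, pos + block.shape[1])
        pos += block.shape[1]
    X = np.hstack(cols)
    if np.linalg.matrix_rank(X) < X.shape[1]:
        # identify the first offending block for the error message
        rank = 1
        ncol = 1
        for v in spec.variables:
            if v.name not in blocks:
                continue
            ncol += len(blocks[v.name])
            r = np.linalg.matrix_rank(X[:, :ncol])
            if r < ncol:
                raise ValidationError(
                    f"design matrix is rank-deficient: block {v.name!r} is "
                    "collinear with preceding columns"
                )
            rank = r
        raise ValidationError("design matrix is rank-deficient")
    return X, blocks
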