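"""Pretreatment of compositional count data.

Raw OTU count tables carry only relative information: the row total is an
artifact of sequencing depth, so Euclidean statistics on raw counts are
spurious.  The standard remedy is the centered log-ratio (clr) transform,
which requires strictly positive parts and therefore a principled zero
replacement first.  The full chain used here is

    counts -> Bayesian-multiplicative zero replacement -> closure -> clr
           -> column standardization

After the chain, each column (feature) has mean 0 and unit sample standard
deviation, which is the form the correlation estimator downstream expects.
For data that is *not* compositional (e.g. plain Gaussian simulations) only
the final standardization applies.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

__all__ = [
    "CountTable",
    "Composition",
    "NormalizedMatrix",
    "bm_replace",
    "closure",
    "clr",
    "normalize",
    "pretreat_pipeline",
    "pretreat_vector",
]

_GROUP_LABELS = ("control", "case", "unlabeled")


@dataclass
class CountTable:
    """A sample x feature matrix of non-negative counts.

    Rows are samples, columns are features (OTUs).  Feature-major files must
    be transposed before construction.
    """

    values: np.ndarray
    sample_ids: list[str] = field(default_factory=list)
    feature_ids: list[str] = field(default_factory=list)
    group_label: str = "unlabeled"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("count table must be a 2-D matrix")
        n, m = self.values.shape
        if m < 2:
            raise ValueError("at least 2 features required (clr undefined for a single part)")
        if not self.sample_ids:
            self.sample_ids = [f"S{i}" for i in range(n)]
        if not self.feature_ids:
            self.feature_ids = [f"F{j}" for j in range(m)]
        if len(self.sample_ids) != n:
            raise ValueError(f"{len(self.sample_ids)} sample ids for {n} rows")
        if len(self.feature_ids) != m:
            raise ValueError(f"{len(self.feature_ids)} feature ids for {m} columns")
        if self.group_label not in _GROUP_LABELS:
            raise ValueError(f"group_label must be one of {_GROUP_LABELS}")
        if np.any(self.values < 0):
            i, j = np.argwhere(self.values < 0)[0]
            raise ValueError(
                f"negative count at sample {self.sample_ids[i]!r}, feature {self.feature_ids[j]!r}"
            )

    @property
    def n_samples(self) -> int:
        return self.values.shape[0]

    @property
    def n_features(self) -> int:
        return self.values.shape[1]


@dataclass
class Composition:
    """Strictly positive matrix whose rows each sum to ``closure_constant``."""

    values: np.ndarray
    closure_constant: float

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.closure_constant <= 0:
            raise ValueError("closure constant must be positive")
        if np.any(self.values <= 0):
            raise ValueError("composition entries must be strictly positive")
        sums = self.values.sum(axis=1)
        if not np.allclose(sums, self.closure_constant, rtol=1e-9):
            raise ValueError("rows do not sum to the closure constant")


@dataclass
class NormalizedMatrix:
    """Column-standardized matrix plus the means/stds that produced it.

    ``source_means`` (b_g) and ``source_stds`` (sigma_g, ddof=1) are kept
    because the incremental-distortion formulas need the group statistics on
    the original (pre-standardization) scale.
    """

    values: np.ndarray
    source_means: np.ndarray
    source_stds: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.source_means = np.asarray(self.source_means, dtype=float)
        self.source_stds = np.asarray(self.source_stds, dtype=float)
        if np.any(self.source_stds <= 0):
            raise ValueError("source stds must be strictly positive")

    @property
    def n_samples(self) -> int:
        return self.values.shape[0]


def _bm_replace_rows(values: np.ndarray) -> np.ndarray:
    """Row-wise Bayesian-multiplicative replacement with the Bayes-Laplace prior."""
    values = np.asarray(values, dtype=float)
    m = values.shape[1]
    out = values.copy()
    row_sums = values.sum(axis=1)
    if np.any(row_sums == 0):
        raise ValueError("degenerate sample: row of all zeros")
    # Bayes-Laplace prior: t = 1/m, s = m, n = row sum.
    for i in np.nonzero((values == 0).any(axis=1))[0]:
        n = row_sums[i]
        zeros = values[i] == 0
        imputed = (1.0 / m) * (m / (n + m))
        total_imputed = zeros.sum() * imputed
        out[i, zeros] = imputed
        out[i, ~zeros] = values[i, ~zeros] * (1.0 - total_imputed)
    return out


def bm_replace(counts: CountTable) -> CountTable:
    """Replace zero counts by prior-weighted pseudo-counts, shrinking nonzeros.

    Zeros in a row become t*s/(n+s) with t = 1/m, s = m and n the row sum;
    nonzero entries are multiplied by one minus the total imputed mass, so the
    replacement is multiplicative and rows without zeros are untouched.
    """
    return CountTable(
        _bm_replace_rows(counts.values),
        sample_ids=list(counts.sample_ids),
        feature_ids=list(counts.feature_ids),
        group_label=counts.group_label,
    )


def closure(x: CountTable | np.ndarray, k: float = 100.0) -> Composition:
    """Rescale each row to sum to the constant ``k``."""
    values = x.values if isinstance(x, CountTable) else np.asarray(x, dtype=float)
    if values.ndim == 1:
        values = values[None, :]
    if k <= 0:
        raise ValueError("closure constant k must be positive")
    if np.any(values <= 0):
        raise ValueError("closure requires strictly positive entries; run zero replacement first")
    return Composition(k * values / values.sum(axis=1, keepdims=True), k)


def clr(x: Composition | np.ndarray) -> np.ndarray:
    """Centered log-ratio transform, row-wise.

    Each entry becomes log(part / geometric mean of the row's parts); output
    rows sum to zero.  Invariant under closure and under any positive rescale
    of a row.  The geometric mean is over the m parts of each sample.
    """
    values = x.values if isinstance(x, Composition) else np.asarray(x, dtype=float)
    squeeze = values.ndim == 1
    if squeeze:
        values = values[None, :]
    if np.any(values <= 0):
        raise ValueError("clr requires strictly positive entries")
    logs = np.log(values)
    out = logs - logs.mean(axis=1, keepdims=True)
    return out[0] if squeeze else out


def normalize(X: np.ndarray, feature_ids: Sequence[str] | None = None) -> NormalizedMatrix:
    """Column-wise z-scoring with sample standard deviations (ddof=1)."""
    X = np.asarray(X, dtype=float)
    if X.shape[0] < 2:
        raise ValueError("at least 2 samples required to standardize")
    means = X.mean(axis=0)
    stds = X.std(axis=0, ddof=1)
    if np.any(stds == 0):
        j = int(np.argwhere(stds == 0)[0][0])
        name = feature_ids[j] if feature_ids is not None else f"column {j}"
        raise ValueError(f"zero-variance feature: {name}")
    return NormalizedMatrix((X - means) / stds, means, stds)


def pretreat_pipeline(counts: CountTable, compositional: bool = True, k: float = 100.0) -> NormalizedMatrix:
    """Full pretreatment chain.

    When ``compositional`` the chain is BM zero replacement, closure to ``k``,
    clr, then standardization; otherwise standardization alone (appropriate
    for already-unconstrained data such as Gaussian simulations, where a
    log-ratio transform would be meaningless and undefined for negatives).
    """
    if compositional:
        X = clr(closure(bm_replace(counts), k=k))
    else:
        X = counts.values
    return normalize(X, feature_ids=counts.feature_ids)


def pretreat_vector(x_p: np.ndarray, compositional: bool = True, k: float = 100.0) -> np.ndarray:
    """Pretreat a single new sample the same way its candidate groups were.

    For compositional data the sample goes through BM replacement, closure and
    clr using its *own* geometric mean; it is not standardized here because the
    distortion formulas center and scale it with the distorted group
    statistics.
    """
    x_p = np.asarray(x_p, dtype=float)
    if x_p.ndim != 1:
        raise ValueError("x_p must be a 1-D vector")
    if not compositional:
        return x_p
    if np.any(x_p < 0):
        raise ValueError("negative entry in sample")
    row = _bm_replace_rows(x_p[None, :])
    return clr(closure(row, k=k))[0]
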