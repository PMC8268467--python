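"""Correlation matrices, spectral decomposition and the phi distortion metric.

phi compares two correlation matrices through their leading eigenpairs: for
each rank j up to the larger of the two retained-component counts it takes
the eigenvalue difference (magnitude deviation) times the principal angle
between the j-th eigenvectors (directional deviation), weighted by the larger
of the two eigenvalues so dominant components contribute proportionally more.
A value of zero means the second matrix leaves the correlation structure of
the first undistorted along every retained component.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["SpectralModel", "correlation", "decompose", "phi"]


@dataclass
class SpectralModel:
    """Eigendecomposition of a correlation matrix plus a retained-component count.

    Eigenvalues are sorted descending; eigenvector columns are unit norm and
    sign-canonicalized so that each column's largest-magnitude entry is
    positive.  ``n_components`` is the number of leading components needed to
    explain the requested share of total variance.
    """

    correlation: np.ndarray
    eigenvalues: np.ndarray
    eigenvectors: np.ndarray
    n_components: int

    @property
    def n_features(self) -> int:
        return self.correlation.shape[0]


def correlation(X_norm) -> np.ndarray:
    """Pearson correlation S = X^T X / (n - 1) of a column-standardized matrix."""
    values = getattr(X_norm, "values", X_norm)
    values = np.asarray(values, dtype=float)
    n = values.shape[0]
    if n < 2:
        raise ValueError("correlation requires at least 2 samples")
    S = values.T @ values / (n - 1)
    return (S + S.T) / 2.0


def _canonicalize_signs(V: np.ndarray) -> np.ndarray:
    """Flip eigenvector columns so the largest-|entry| of each is positive."""
    idx = np.argmax(np.abs(V), axis=0)
    signs = np.sign(V[idx, np.arange(V.shape[1])])
    signs[signs == 0] = 1.0
    return V * signs


def n_components_for(eigenvalues: np.ndarray, alpha: float) -> int:
    """Smallest a such that the top-a eigenvalues explain >= 100(1-alpha)% of variance."""
    lam = np.asarray(eigenvalues, dtype=float)
    total = lam.sum()
    frac = np.cumsum(lam) / total
    # tiny slack so an exact boundary (e.g. identity spectrum) is not missed
    hits = np.nonzero(frac >= (1.0 - alpha) - 1e-12)[0]
    return int(hits[0]) + 1 if hits.size else lam.size


def decompose(S: np.ndarray, alpha: float = 0.05) -> SpectralModel:
    """Eigendecompose a symmetric matrix and select the leading components.

    ``alpha`` is the share of total variance allowed to be discarded: the
    retained count is the smallest a whose cumulative eigenvalue fraction
    reaches 1 - alpha.
    """
    S = np.asarray(S, dtype=float)
    if S.ndim != 2 or S.shape[0] != S.shape[1]:
        raise ValueError("decompose requires a square matrix")
    if np.max(np.abs(S - S.T)) > 1e-8:
        raise ValueError("decompose requires a symmetric matrix")
    if not 0.0 < alpha < 1.0:
        raise ValueError("alpha must lie in (0, 1)")
    lam, V = np.linalg.eigh((S + S.T) / 2.0)
    order = np.argsort(lam)[::-1]
    lam = lam[order]
    V = _canonicalize_signs(V[:, order])
    return SpectralModel(S, lam, V, n_components_for(lam, alpha))


def phi(model_ref: SpectralModel, model_new: SpectralModel) -> float:
    """Correlation-structure distortion between two spectral models.

    Sums, over ranks j up to max of the two component counts, the product of
    the larger eigenvalue, the eigenvalue difference (reference minus new) and
    the principal angle between the rank-matched eigenvectors.  The inner
    product is taken in absolute value before arccos because eigenvector sign
    is arbitrary; the result is the angle in [0, pi/2].
    """
    if model_ref.n_features != model_new.n_features:
        raise ValueError("models must share the feature space")
    jmax = max(model_ref.n_components, model_new.n_components)
    lam_r = model_ref.eigenvalues[:jmax]
    lam_n = model_new.eigenvalues[:jmax]
    dots = np.abs(np.einsum("ij,ij->j", model_ref.eigenvectors[:, :jmax], model_new.eigenvectors[:, :jmax]))
    angles = np.arccos(np.clip(dots, 0.0, 1.0))
    return float(np.sum(np.maximum(lam_r, lam_n) * (lam_r - lam_n) * angles))
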