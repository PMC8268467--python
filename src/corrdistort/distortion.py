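"""Exact rank-one correlation update with artificial dimensional reduction.

Incorporating one new sample x_p into a group of n_g samples changes the
group mean, the per-feature standard deviations and the correlation matrix in
closed form, without touching the raw data matrix:

    b~      = n/(n+1) b  +  1/(n+1) x_p
    sigma~_i = sqrt( (n-1)/n sigma_i^2 + db_i^2 + 1/n (x_p_i - b~_i)^2 )
    S~      = (n-1)/n D S D  +  u u^T  +  1/n  z z^T

with db = b~ - b, D = diag(sigma) diag(sigma~)^-1, u = db / sigma~ and
z = (x_p - b~) / sigma~.  At the true n_g this reproduces, exactly, the
Pearson correlation of the augmented matrix [X_g; x_p].

The "artificial dimensional reduction" replaces n_g by a smaller effective
count n_red in every weight quotient above, while b, sigma and S keep being
the full-group statistics.  A large group would otherwise swamp the new
sample (at n = 200 its natural weight is ~0.005); shrinking n_red makes one
sample's influence comparable and tunable across groups of unequal size.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .pretreat import NormalizedMatrix, normalize
from .spectral import SpectralModel, correlation, decompose

__all__ = [
    "GroupSummary",
    "DistortionResult",
    "distorted_mean",
    "distorted_std",
    "distorted_correlation",
    "distortion_profile",
    "phi_profile_batch",
    "reduced_dimension_sequence",
]


@dataclass
class GroupSummary:
    """Sufficient statistics of one group: n_g, mean b_g, stds sigma_g, correlation S_g."""

    n_g: int
    b_g: np.ndarray
    sigma_g: np.ndarray
    S_g: np.ndarray

    def __post_init__(self) -> None:
        self.b_g = np.asarray(self.b_g, dtype=float)
        self.sigma_g = np.asarray(self.sigma_g, dtype=float)
        self.S_g = np.asarray(self.S_g, dtype=float)
        if self.n_g < 2:
            raise ValueError("group must contain at least 2 samples")
        if np.any(self.sigma_g <= 0):
            raise ValueError("all group standard deviations must be positive")
        if np.max(np.abs(self.S_g - self.S_g.T)) > 1e-8:
            raise ValueError("correlation matrix must be symmetric")

    @property
    def n_features(self) -> int:
        return self.b_g.size

    @classmethod
    def from_matrix(cls, X: np.ndarray) -> "GroupSummary":
        """Build the summary from a (pretreated but unstandardized) data matrix."""
        return cls.from_normalized(normalize(np.asarray(X, dtype=float)))

    @classmethod
    def from_normalized(cls, X_norm: NormalizedMatrix) -> "GroupSummary":
        return cls(
            n_g=X_norm.n_samples,
            b_g=X_norm.source_means,
            sigma_g=X_norm.source_stds,
            S_g=correlation(X_norm),
        )


@dataclass
class DistortionResult:
    """Distorted statistics and phi for one (group, sample, n_red) triple."""

    n_red: int
    b_tilde: np.ndarray
    sigma_tilde: np.ndarray
    S_tilde: np.ndarray
    phi_value: float = float("nan")


def _check_vector(summary: GroupSummary, x_p: np.ndarray) -> np.ndarray:
    x_p = np.asarray(x_p, dtype=float)
    if x_p.shape != (summary.n_features,):
        raise ValueError(f"sample has {x_p.size} features, group has {summary.n_features}")
    return x_p


def distorted_mean(summary: GroupSummary, x_p: np.ndarray, n_eff: int) -> np.ndarray:
    """Mean after incorporating x_p, with weights n_eff/(n_eff+1) and 1/(n_eff+1)."""
    x_p = _check_vector(summary, x_p)
    if n_eff < 2:
        raise ValueError("effective sample count must be at least 2")
    w1 = n_eff / (n_eff + 1.0)
    return w1 * summary.b_g + (1.0 - w1) * x_p


def distorted_std(summary: GroupSummary, x_p: np.ndarray, b_tilde: np.ndarray, n_eff: int) -> np.ndarray:
    """Per-feature standard deviation after incorporating x_p."""
    x_p = _check_vector(summary, x_p)
    b_tilde = np.asarray(b_tilde, dtype=float)
    if n_eff < 2:
        raise ValueError("effective sample count must be at least 2")
    db = b_tilde - summary.b_g
    var = ((n_eff - 1.0) / n_eff) * summary.sigma_g**2 + db**2 + (x_p - b_tilde) ** 2 / n_eff
    return np.sqrt(var)


def distorted_correlation(summary: GroupSummary, x_p: np.ndarray, n_eff: int) -> DistortionResult:
    """Distorted correlation matrix with the group size replaced by n_eff.

    The three-term update: the original correlation rescaled by the old/new
    standard deviations (weight (n_eff-1)/n_eff), the mean-shift outer product
    and the standardized new sample's outer product (weight 1/n_eff).  With
    n_eff equal to the true group size this is exactly the correlation of the
    augmented matrix.
    """
    x_p = _check_vector(summary, x_p)
    b_tilde = distorted_mean(summary, x_p, n_eff)
    sigma_tilde = distorted_std(summary, x_p, b_tilde, n_eff)
    if np.any(sigma_tilde == 0):
        raise ValueError("distorted standard deviation vanished for a feature")
    d = summary.sigma_g / sigma_tilde
    u = (b_tilde - summary.b_g) / sigma_tilde
    z = (x_p - b_tilde) / sigma_tilde
    S_tilde = (
        ((n_eff - 1.0) / n_eff) * (np.outer(d, d) * summary.S_g)
        + np.outer(u, u)
        + np.outer(z, z) / n_eff
    )
    S_tilde = (S_tilde + S_tilde.T) / 2.0
    return DistortionResult(n_eff, b_tilde, sigma_tilde, S_tilde)


def reduced_dimension_sequence(n_max: int, delta_n: int) -> np.ndarray:
    """The arithmetic sequence of artificial dimensions (2, 2+dn, ..., n_max)."""
    if delta_n < 1:
        raise ValueError("delta_n must be a positive integer")
    if n_max < 2:
        raise ValueError("n_max must be at least 2")
    if (n_max - 2) % delta_n != 0:
        raise ValueError(
            f"(n_max - 2) = {n_max - 2} is not divisible by delta_n = {delta_n}; "
            f"lower n_max to {2 + ((n_max - 2) // delta_n) * delta_n} or change delta_n"
        )
    return np.arange(2, n_max + 1, delta_n)


def distortion_profile(
    summary: GroupSummary,
    x_p: np.ndarray,
    n_max: int,
    delta_n: int = 1,
    alpha: float = 0.05,
    reference: SpectralModel | None = None,
) -> list[DistortionResult]:
    """Distortion results over every artificial dimension in (2, 2+dn, ..., n_max).

    Each result carries phi between the group's spectral model and that of its
    distorted correlation matrix.  ``reference`` lets callers reuse an
    existing decomposition of S_g.
    """
    x_p = _check_vector(summary, x_p)
    if n_max > summary.n_g:
        raise ValueError("n_max cannot exceed the group sample count")
    n_reds = reduced_dimension_sequence(n_max, delta_n)
    if reference is None:
        reference = decompose(summary.S_g, alpha)
    results = []
    phis = phi_profile_batch(summary, x_p[None, :], n_reds, alpha, reference)[0]
    for n_red, phi_val in zip(n_reds, phis):
        res = distorted_correlation(summary, x_p, int(n_red))
        res.phi_value = float(phi_val)
        results.append(res)
    return results


def _distorted_corr_stack(summary: GroupSummary, X_new: np.ndarray, n_reds: np.ndarray) -> np.ndarray:
    """Distorted correlation matrices for R samples x K reduced dimensions, (R, K, m, m)."""
    b = summary.b_g
    sig = summary.sigma_g
    S = summary.S_g
    n = n_reds.astype(float)[None, :, None]          # (1, K, 1)
    x = X_new[:, None, :]                            # (R, 1, m)
    w1 = n / (n + 1.0)
    b_t = w1 * b + (1.0 - w1) * x                    # (R, K, m)
    db = b_t - b
    resid = x - b_t
    sig_t = np.sqrt(((n - 1.0) / n) * sig**2 + db**2 + resid**2 / n)
    d = sig / sig_t
    u = db / sig_t
    z = resid / sig_t
    S_t = (
        ((n - 1.0) / n)[..., None] * (d[..., :, None] * d[..., None, :] * S)
        + u[..., :, None] * u[..., None, :]
        + (z[..., :, None] * z[..., None, :]) / n[..., None]
    )
    return S_t


def phi_profile_batch(
    summary: GroupSummary,
    X_new: np.ndarray,
    n_reds: np.ndarray,
    alpha: float = 0.05,
    reference: SpectralModel | None = None,
) -> np.ndarray:
    """phi(S_g, S~_g) for a batch of new samples across all reduced dimensions.

    Returns an (R, K) array for R samples and K artificial dimensions.  The
    eigendecompositions are batched, which is what makes whole-table
    classification tractable; the arithmetic is identical to the scalar path
    through :func:`distorted_correlation` and :func:`~corrdistort.spectral.phi`.
    """
    X_new = np.atleast_2d(np.asarray(X_new, dtype=float))
    n_reds = np.asarray(n_reds)
    if reference is None:
        reference = decompose(summary.S_g, alpha)
    R, m = X_new.shape
    K = n_reds.size
    # chunk rows so the (chunk, K, m, m) stack stays within ~64 MB
    chunk = max(1, int(64e6 / max(K * m * m * 8, 1)))
    out = np.empty((R, K))
    for start in range(0, R, chunk):
        rows = X_new[start : start + chunk]
        S_t = _distorted_corr_stack(summary, rows, n_reds)
        lam, V = np.linalg.eigh(S_t)                 # ascending
        lam = lam[..., ::-1]                         # (r, K, m) descending
        V = V[..., ::-1]
        # retained components per distorted model
        totals = lam.sum(axis=-1, keepdims=True)
        frac = np.cumsum(lam, axis=-1) / totals
        a_new = np.argmax(frac >= (1.0 - alpha) - 1e-12, axis=-1) + 1
        jmax = np.maximum(a_new, reference.n_components)
        lam_r = reference.eigenvalues                # (m,)
        dots = np.abs(np.einsum("ij,rkij->rkj", reference.eigenvectors, V))
        angles = np.arccos(np.clip(dots, 0.0, 1.0))
        terms = np.maximum(lam_r, lam) * (lam_r - lam) * angles
        mask = np.arange(m) < jmax[..., None]
        out[start : start + chunk] = np.sum(terms * mask, axis=-1)
    return out
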