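"""Synthetic two-group data with equicorrelation (compound-symmetry) structure.

Each group is drawn from a zero-mean multivariate Normal whose covariance is
the generatrix matrix (1 - rho) I + rho 11^T: unit variances, constant
pairwise correlation rho.  The two groups differ only in rho (defaults 0.1
for control, 0.2 for case), so any classification signal comes purely from
the correlation structure, which is exactly what the distortion classifier
probes.  The draws are unconstrained Gaussians, not compositions, so the
log-ratio pretreatment is not applied to them.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["SimulationConfig", "generatrix", "sample_pair"]


@dataclass
class SimulationConfig:
    """Grid of simulation settings: sample sizes, feature counts, group correlations."""

    n_values: list[int] = field(default_factory=lambda: [20, 40, 60, 80, 100, 120, 140, 160])
    m_values: list[int] = field(default_factory=lambda: [20, 40, 60, 80, 100, 120, 140])
    rho_c: float = 0.1
    rho_v: float = 0.2
    n_replicates: int = 100
    seed: int = 0

    def __post_init__(self) -> None:
        if any(n < 4 for n in self.n_values):
            raise ValueError("sample sizes must be at least 4")
        if any(m < 2 for m in self.m_values):
            raise ValueError("feature counts must be at least 2")
        if self.n_replicates < 1:
            raise ValueError("need at least one replicate")
        m_max = max(self.m_values)
        for rho in (self.rho_c, self.rho_v):
            if not -1.0 / (m_max - 1) < rho < 1.0:
                raise ValueError(f"rho = {rho} makes the generatrix non positive definite")


def generatrix(m: int, rho: float) -> np.ndarray:
    """Equicorrelation matrix (1 - rho) I_m + rho 1 1^T.

    Positive definite iff -1/(m-1) < rho < 1; eigenvalues are 1 + (m-1) rho
    (once) and 1 - rho (with multiplicity m - 1).
    """
    if m < 2:
        raise ValueError("m must be at least 2")
    if not -1.0 / (m - 1) < rho < 1.0:
        raise ValueError(f"rho = {rho} outside the positive-definite range (-1/(m-1), 1)")
    return (1.0 - rho) * np.eye(m) + rho * np.ones((m, m))


def sample_pair(
    config: SimulationConfig, n: int, m: int, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    """Draw one (control, case) pair of n x m Gaussian matrices.

    Sampling goes through the Cholesky factor of each generatrix for speed and
    cross-platform reproducibility under a seeded generator.
    """
    L_c = np.linalg.cholesky(generatrix(m, config.rho_c))
    L_v = np.linalg.cholesky(generatrix(m, config.rho_v))
    X_c = rng.standard_normal((n, m)) @ L_c.T
    X_v = rng.standard_normal((n, m)) @ L_v.T
    return X_c, X_v
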