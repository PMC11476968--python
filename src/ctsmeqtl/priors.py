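"""Prior specifications and hyperparameters for the hierarchical model.

The K interaction coefficients (the cell-type-specific genotype effects)
receive a hierarchical double-exponential scale-mixture prior centred at a
mean vector ``mu`` with a correlation structure ``rho``; every other
coefficient (covariates, proportion main effects, intercept) is a nuisance
parameter with a fixed diffuse normal prior and is effectively unpenalised.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

PD_EIG_FLOOR = 1e-8


def repair_correlation(rho: np.ndarray, eig_floor: float = PD_EIG_FLOOR) -> np.ndarray:
    """Return the nearest convenient positive-definite correlation matrix.

    Symmetrises, clips eigenvalues at ``eig_floor`` and rescales to unit
    diagonal, iterating because the rescaling can push the smallest
    eigenvalue back below the floor.
    """
    R = np.asarray(rho, dtype=float)
    R = 0.5 * (R + R.T)
    K = R.shape[0]
    for _ in range(100):
        vals, vecs = np.linalg.eigh(R)
        if vals.min() >= eig_floor and np.allclose(np.diag(R), 1.0, atol=1e-12):
            return R
        # clip above the floor so the unit-diagonal rescale (a congruence by
        # diag entries <= K) cannot push the smallest eigenvalue back under it
        vals = np.clip(vals, eig_floor * K, None)
        R = (vecs * vals) @ vecs.T
        d = np.sqrt(np.diag(R))
        R = R / np.outer(d, d)
        np.fill_diagonal(R, 1.0)
        R = 0.5 * (R + R.T)
    raise np.linalg.LinAlgError("correlation repair did not converge")


@dataclass
class PriorSpec:
    """Prior location and correlation for the K interaction coefficients."""

    mu: np.ndarray
    rho: np.ndarray
    nuisance_variance: float = 1e8
    nuisance_mean: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.mu = np.asarray(self.mu, dtype=float).ravel()
        K = self.mu.shape[0]
        rho = np.asarray(self.rho, dtype=float)
        if rho.shape != (K, K):
            raise ValueError(f"rho must be {K}x{K}")
        if np.any(np.abs(rho) > 1 + 1e-9):
            raise ValueError("correlation entries must lie in [-1, 1]")
        self.rho = repair_correlation(rho)
        if self.nuisance_variance <= 0:
            raise ValueError("nuisance_variance must be positive")
        if self.nuisance_mean is not None:
            self.nuisance_mean = np.asarray(self.nuisance_mean, dtype=float).ravel()

    @property
    def n_celltypes(self) -> int:
        return self.mu.shape[0]

    @property
    def rho_inv(self) -> np.ndarray:
        return np.linalg.inv(self.rho)


def uninformative_prior(n_celltypes: int, nuisance_variance: float = 1e8) -> PriorSpec:
    """Zero-mean, uncorrelated prior: the default when no sorted-cell data exist."""
    return PriorSpec(
        mu=np.zeros(n_celltypes),
        rho=np.eye(n_celltypes),
        nuisance_variance=nuisance_variance,
    )


@dataclass
class HyperParams:
    """Gamma hyper-prior ``s_k ~ Gamma(a, b_k)`` and fitting controls.

    Smaller ``b_k`` concentrates the shrinkage scale at larger values and
    hence penalises the corresponding cell type's effect more weakly; large
    ``b_k`` induces a nearly flat penalty.  ``beta_floor`` bounds
    ``|beta_k - mu_k|`` away from zero in the E-step denominators.
    """

    a: float = 0.5
    b: float | np.ndarray = 0.2
    delta: float = 1e-5
    max_iter: int = 500
    beta_floor: float = 1e-8

    def __post_init__(self) -> None:
        if self.a <= 0:
            raise ValueError("a must be positive")
        if np.any(np.asarray(self.b, dtype=float) <= 0):
            raise ValueError("b must be positive")
        if self.delta <= 0 or self.beta_floor <= 0:
            raise ValueError("delta and beta_floor must be positive")
        if self.max_iter < 1:
            raise ValueError("max_iter must be >= 1")

    def rates(self, n_celltypes: int) -> np.ndarray:
        b = np.asarray(self.b, dtype=float)
        if b.ndim == 0:
            return np.full(n_celltypes, float(b))
        if b.shape[0] != n_celltypes:
            raise ValueError(f"b must be scalar or length {n_celltypes}")
        return b


def default_rates(mean_proportions, lo: float = 0.05, hi: float = 0.10) -> np.ndarray:
    """Per-cell-type Gamma rates ``b_k`` for moderate sample sizes.

    Abundant cell types (mean proportion above ``hi``) get ``b_k = 0.2``
    (informative shrinkage); rare ones (below ``lo``) get ``b_k = 5`` so the
    prior stays weak and cannot dominate a coefficient that the data barely
    identify.  Proportions in between interpolate linearly.
    """
    p = np.asarray(mean_proportions, dtype=float)
    frac = np.clip((hi - p) / (hi - lo), 0.0, 1.0)
    return 0.2 + frac * (5.0 - 0.2)
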