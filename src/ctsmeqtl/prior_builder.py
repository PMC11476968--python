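"""Derive informative priors from small-sample sorted-cell methylation data.

For each cell type with sorted-cell (cell-type-specific, CTS) methylation,
the per-SNP effect ``beta_seq`` is estimated by regressing the cell type's
methylome at the CpG on the genotype dosage.  The prior mean is the
multiplicity-weighted estimate

    mu_k = (1 - p_adjust) * beta_seq,

so noisy small-sample estimates are pulled toward zero.  Cross-cell-type
prior correlations are weighted the same way.  Cell types without sorted
data keep ``mu_k = 0`` and zero correlation, reproducing the uninformative
prior exactly.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .priors import PriorSpec, repair_correlation

logger = logging.getLogger(__name__)

MIN_SAMPLES = 3


@dataclass
class PriorEstimate:
    """One cell type's sorted-cell effect estimate and its shrinkage weight."""

    beta_seq: float
    p_raw: float
    p_adjust: float

    @property
    def weight(self) -> float:
        return 1.0 - self.p_adjust


def estimate_cts_effect(cts_meth, genotype, covariates=None) -> tuple[float, float]:
    """Slope and two-sided p-value of CTS methylation regressed on dosage.

    Uses least squares with a t reference on the residual degrees of
    freedom.  Degenerate inputs (constant genotype, < 3 usable samples,
    all-missing methylation) return ``(0.0, 1.0)``.
    """
    y = np.asarray(cts_meth, dtype=float).ravel()
    g = np.asarray(genotype, dtype=float).ravel()
    if y.shape != g.shape:
        raise ValueError("methylation/genotype length mismatch")
    keep = np.isfinite(y) & np.isfinite(g)
    if covariates is not None:
        Xc = np.asarray(covariates, dtype=float)
        if Xc.ndim == 1:
            Xc = Xc[:, None]
        keep &= np.all(np.isfinite(Xc), axis=1)
    if keep.sum() == 0:
        logger.warning("all methylation values missing; returning null effect")
        return 0.0, 1.0
    y, g = y[keep], g[keep]
    if y.shape[0] < MIN_SAMPLES or np.ptp(g) == 0.0:
        return 0.0, 1.0
    X = np.column_stack([np.ones_like(g), g])
    if covariates is not None:
        X = np.column_stack([X, Xc[keep]])
    n, q = X.shape
    if n <= q:
        return 0.0, 1.0
    coef, _, rank, _ = np.linalg.lstsq(X, y, rcond=None)
    if rank < q:
        return 0.0, 1.0
    resid = y - X @ coef
    sigma2 = float(resid @ resid) / (n - q)
    XtX_inv = np.linalg.inv(X.T @ X)
    se = np.sqrt(max(sigma2 * XtX_inv[1, 1], 0.0))
    if se == 0.0:
        return float(coef[1]), 0.0
    tval = coef[1] / se
    p = 2.0 * stats.t.sf(abs(tval), n - q)
    return float(coef[1]), float(p)


def adjust_pvalues(p_values, method: str = "bonferroni", n_tests: int | None = None) -> np.ndarray:
    """Adjusted p-values by Bonferroni or Benjamini-Hochberg step-up.

    ``n_tests`` overrides the family size for Bonferroni (e.g. when only a
    subset of a larger testing family is passed in); BH always uses the
    supplied vector.
    """
    p = np.atleast_1d(np.asarray(p_values, dtype=float))
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    if method == "bonferroni":
        m = int(n_tests) if n_tests is not None else p.shape[0]
        if m < 1:
            raise ValueError("n_tests must be >= 1")
        return np.minimum(p * m, 1.0)
    if method == "bh":
        return multipletests(p, method="fdr_bh")[1]
    raise ValueError(f"unknown method {method!r}")


def shrinkage_weight(p_raw: float, n_tests: int = 1, method: str = "bonferroni"):
    """Weight ``1 - p_adjust`` attached to a sorted-cell estimate.

    For BH the full p-value vector must be supplied (an array argument);
    the return then matches elementwise.
    """
    adj = adjust_pvalues(p_raw, method=method, n_tests=n_tests)
    w = 1.0 - adj
    return float(w[0]) if np.isscalar(p_raw) and w.shape == (1,) else w


def estimate_prior_correlation(cts_meth_j, cts_meth_k) -> tuple[float, float]:
    """Cross-cell-type correlation of methylation over shared samples.

    Pearson correlation with the standard t-based p-value.  This is a
    documented proxy for the genetic correlation between the two cell
    types' methylomes; swap in another estimator by passing its
    ``(rho_hat, p)`` directly to :func:`build_prior`.
    """
    a = np.asarray(cts_meth_j, dtype=float).ravel()
    b = np.asarray(cts_meth_k, dtype=float).ravel()
    if a.shape != b.shape:
        raise ValueError("cell-type vectors must share samples")
    keep = np.isfinite(a) & np.isfinite(b)
    a, b = a[keep], b[keep]
    if a.shape[0] < MIN_SAMPLES or np.ptp(a) == 0.0 or np.ptp(b) == 0.0:
        return 0.0, 1.0
    r, p = stats.pearsonr(a, b)
    return float(r), float(p)


def build_prior(
    estimates: dict[int, PriorEstimate] | list[PriorEstimate | None],
    correlations: dict[tuple[int, int], tuple[float, float]] | None = None,
    n_celltypes: int | None = None,
    nuisance_variance: float = 1e8,
) -> PriorSpec:
    """Combine weighted sorted-cell estimates into a PriorSpec.

    Parameters
    ----------
    estimates : per-cell-type :class:`PriorEstimate`; entries may be None
        (or absent from a dict) for cell types without sorted data, which
        then contribute ``mu_k = 0``.
    correlations : mapping ``(j, k) -> (rho_hat, weight)`` of pairwise
        weighted correlations (0-based indices); missing pairs are 0.
    """
    if isinstance(estimates, dict):
        if n_celltypes is None:
            n_celltypes = max(estimates) + 1 if estimates else 0
        est_list: list[PriorEstimate | None] = [estimates.get(k) for k in range(n_celltypes)]
    else:
        est_list = list(estimates)
        n_celltypes = len(est_list)
    K = n_celltypes
    mu = np.zeros(K)
    for k, e in enumerate(est_list):
        if e is not None:
            mu[k] = e.weight * e.beta_seq
    rho = np.eye(K)
    if correlations:
        for (j, k), (rho_hat, w) in correlations.items():
            if j == k:
                continue
            rho[j, k] = rho[k, j] = w * rho_hat
    rho = repair_correlation(rho)
    return PriorSpec(mu=mu, rho=rho, nuisance_variance=nuisance_variance)


def build_snp_priors(
    cts_meth: np.ndarray,
    genotypes: np.ndarray,
    n_tests: int | None = None,
    method: str = "bonferroni",
    corr_n_tests: int = 1,
    nuisance_variance: float = 1e8,
) -> list[PriorSpec]:
    """Per-SNP priors for one CpG from a sorted-cell subset.

    Parameters
    ----------
    cts_meth : (m, K) sorted-cell methylation at the CpG for the m subset
        samples.
    genotypes : (m, p) dosages for the same samples.
    n_tests : Bonferroni family size for the effect p-values; defaults to
        the number of SNPs tested here.
    corr_n_tests : family size for the correlation p-values (the number of
        CpGs when correlations are estimated once per CpG).

    Returns
    -------
    list of PriorSpec, one per SNP column.
    """
    cts_meth = np.asarray(cts_meth, dtype=float)
    genotypes = np.asarray(genotypes, dtype=float)
    m, K = cts_meth.shape
    p = genotypes.shape[1]
    if genotypes.shape[0] != m:
        raise ValueError("sorted-cell methylation and genotypes must share samples")
    family = n_tests if n_tests is not None else p

    # pairwise methylation correlations are per-CpG, shared by all SNPs
    correlations: dict[tuple[int, int], tuple[float, float]] = {}
    for j in range(K):
        for k in range(j + 1, K):
            rho_hat, p_rho = estimate_prior_correlation(cts_meth[:, j], cts_meth[:, k])
            w = float(shrinkage_weight(p_rho, n_tests=corr_n_tests, method=method))
            correlations[(j, k)] = (rho_hat, w)

    beta_seq = np.zeros((p, K))
    p_raw = np.ones((p, K))
    for s in range(p):
        for k in range(K):
            beta_seq[s, k], p_raw[s, k] = estimate_cts_effect(
                cts_meth[:, k], genotypes[:, s]
            )
    # adjust within cell type: Bonferroni over the declared family, BH over
    # the SNPs actually tested here
    p_adj = np.ones_like(p_raw)
    for k in range(K):
        if method == "bonferroni":
            p_adj[:, k] = adjust_pvalues(p_raw[:, k], method=method, n_tests=family)
        else:
            p_adj[:, k] = adjust_pvalues(p_raw[:, k], method=method)

    priors = []
    for s in range(p):
        ests = [
            PriorEstimate(
                beta_seq=float(beta_seq[s, k]),
                p_raw=float(p_raw[s, k]),
                p_adjust=float(p_adj[s, k]),
            )
            for k in range(K)
        ]
        priors.append(
            build_prior(ests, correlations, nuisance_variance=nuisance_variance)
        )
    return priors
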