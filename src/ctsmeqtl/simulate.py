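"""Seeded generator for cell-type-specific meQTL simulation studies.

One simulated locus is a CpG with a window of SNPs.  A subset of SNPs is
causal for methylation in designated cell types; per-cell-type methylomes
are linear in genotype with heritability calibrated empirically, bulk
methylation is the proportion-weighted mixture of the cell-type methylomes
plus Gaussian noise, and cell-type proportions follow a Dirichlet law whose
parameters mimic blood cell composition variability.

Three effect-sharing scenarios are supported: effects confined to the most
abundant cell type (1), to the least abundant cell type (2), or correlated
effects in all cell types (3).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

H2_TOL = 0.005


@dataclass
class ScenarioConfig:
    """Study conditions for one simulation setting.

    Defaults follow the reference simulation design: 500 SNPs per locus,
    methylation heritability 0.3 in causal cell types, three cell types with
    Dirichlet(5.30, 1.27, 1.62) proportions, bulk mixing noise N(0, 0.01),
    and a 5% sorted-cell subset.
    """

    scenario: int = 1
    n_samples: int = 4000
    n_snps: int = 500
    prop_causal: float = 0.10
    maf_range: tuple[float, float] = (0.01, 0.5)
    ld_rho: float = 0.0
    h2: float = 0.3
    K: int = 3
    dirichlet_alpha: tuple[float, ...] = (5.30, 1.27, 1.62)
    genetic_corr: float = 0.5
    bulk_noise_var: float = 0.01
    cts_subset_frac: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        if self.scenario not in (1, 2, 3):
            raise ValueError("scenario must be 1, 2 or 3")
        if not 0 < self.prop_causal <= 1:
            raise ValueError("prop_causal must lie in (0, 1]")
        if not 0 < self.h2 < 1:
            raise ValueError("h2 must lie in (0, 1)")
        if not 0 <= self.ld_rho < 1:
            raise ValueError("ld_rho must lie in [0, 1)")
        alpha = np.asarray(self.dirichlet_alpha, dtype=float)
        if alpha.shape[0] != self.K or np.any(alpha <= 0):
            raise ValueError("dirichlet_alpha must be K positive values")


@dataclass
class SimulatedDataset:
    """Genotypes, ground-truth effects, cell-type and bulk methylomes."""

    genotypes: np.ndarray  # (n, p) dosages
    true_effects: np.ndarray  # (p, K), cell-means scale
    cts_meth: np.ndarray  # (n, K)
    proportions: np.ndarray  # (n, K)
    bulk: np.ndarray  # (n,)
    epsilon: np.ndarray  # (n,) stored mixing noise
    cts_subset_index: np.ndarray  # sorted sample indices with sorted-cell data
    mafs: np.ndarray = field(default_factory=lambda: np.empty(0))
    causal_index: np.ndarray = field(default_factory=lambda: np.empty(0, dtype=int))


def _latent_corr_for(target: float, maf1: float, maf2: float) -> float:
    """Latent Gaussian correlation whose thresholded alleles correlate at ``target``."""
    h1 = stats.norm.ppf(1.0 - maf1)
    h2 = stats.norm.ppf(1.0 - maf2)
    denom = np.sqrt(maf1 * (1 - maf1) * maf2 * (1 - maf2))

    def allele_corr(r: float) -> float:
        p11 = stats.multivariate_normal(
            mean=[0.0, 0.0], cov=[[1.0, r], [r, 1.0]]
        ).cdf([-h1, -h2])  # P(Z1 > h1, Z2 > h2) by symmetry
        return (p11 - maf1 * maf2) / denom

    lo, hi = target, 0.9999
    if allele_corr(hi) <= target:
        return hi
    for _ in range(40):
        mid = 0.5 * (lo + hi)
        if allele_corr(mid) < target:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


def simulate_genotypes(config: ScenarioConfig, rng: np.random.Generator | None = None):
    """Dosage matrix with per-SNP MAF uniform on ``maf_range``.

    With ``ld_rho = 0`` alleles are independent binomial draws under
    Hardy-Weinberg.  With ``ld_rho > 0`` two haplotypes per sample follow a
    latent Gaussian AR(1) chain across SNPs, thresholded at each SNP's MAF;
    the latent correlation is calibrated so adjacent *genotype* correlation
    matches ``ld_rho`` (thresholding attenuates latent correlation).

    Returns ``(genotypes, mafs)``.
    """
    rng = rng or np.random.default_rng(config.seed)
    n, p = config.n_samples, config.n_snps
    mafs = rng.uniform(*config.maf_range, size=p)
    if config.ld_rho == 0.0:
        geno = rng.binomial(2, mafs[None, :], size=(n, p)).astype(float)
        return geno, mafs
    r_latent = np.array(
        [_latent_corr_for(config.ld_rho, mafs[j], mafs[j + 1]) for j in range(p - 1)]
    )
    thresholds = stats.norm.ppf(1.0 - mafs)
    geno = np.zeros((n, p))
    for _ in range(2):  # two haplotypes
        z = np.empty((n, p))
        z[:, 0] = rng.standard_normal(n)
        innov = rng.standard_normal((n, p - 1))
        for j in range(1, p):
            r = r_latent[j - 1]
            z[:, j] = r * z[:, j - 1] + np.sqrt(1.0 - r * r) * innov[:, j - 1]
        geno += (z > thresholds[None, :]).astype(float)
    return geno, mafs


def simulate_effects(config: ScenarioConfig, rng: np.random.Generator | None = None):
    """True effect matrix (p, K) under the configured sharing scenario.

    Exactly ``round(prop_causal * p)`` SNPs are causal.  Scenario 1 places
    standard-normal effects in the most abundant cell type only, scenario 2
    in the least abundant only, scenario 3 draws causal rows from a
    K-variate normal with compound-symmetric correlation ``genetic_corr``.
    The overall scale is irrelevant: heritability calibration rescales it.

    Returns ``(effects, causal_index)``.
    """
    rng = rng or np.random.default_rng(config.seed)
    p, K = config.n_snps, config.K
    n_causal = int(round(config.prop_causal * p))
    causal = np.sort(rng.choice(p, size=n_causal, replace=False))
    effects = np.zeros((p, K))
    alpha = np.asarray(config.dirichlet_alpha)
    if config.scenario == 1:
        effects[causal, int(np.argmax(alpha))] = rng.standard_normal(n_causal)
    elif config.scenario == 2:
        effects[causal, int(np.argmin(alpha))] = rng.standard_normal(n_causal)
    else:
        cov = np.full((K, K), config.genetic_corr)
        np.fill_diagonal(cov, 1.0)
        effects[causal] = rng.multivariate_normal(np.zeros(K), cov, size=n_causal)
    return effects, causal


def _calibrated_column(g: np.ndarray, e: np.ndarray, h2: float) -> tuple[float, np.ndarray]:
    """Scale factor c such that var(c*g) / var(c*g + e) equals h2 empirically."""
    vg = g.var()
    ve = e.var()
    cge = np.cov(g, e, ddof=0)[0, 1]
    disc = h2 * h2 * cge * cge + vg * (1.0 - h2) * h2 * ve
    c = (h2 * cge + np.sqrt(disc)) / (vg * (1.0 - h2))
    return c, c * g + e


def simulate_cts_and_bulk(
    genotypes: np.ndarray,
    effects: np.ndarray,
    config: ScenarioConfig,
    rng: np.random.Generator | None = None,
) -> SimulatedDataset:
    """Cell-type methylomes, proportions and mixed bulk signal.

    Effects act on the *standardised* genotype scale (the convention of
    variance-component simulators): each causal SNP contributes
    ``u_jk * (g_j - mean) / sd``, so rarer variants carry larger
    dosage-scale effects and comparable variance explained.  Each causal
    cell type's methylome is this genetic value plus normal noise, with the
    effect column rescaled so the realised heritability equals ``h2``
    (machine precision; the contract allows 0.005) and the total variance
    standardised to 1.  Non-causal cell types receive pure noise of the
    same total variance.  Bulk mixes the methylomes with Dirichlet
    proportions plus ``N(0, bulk_noise_var)`` noise.  ``true_effects`` in
    the returned dataset is reported on the dosage (cell-means model)
    scale, directly comparable to fitted interaction coefficients.
    """
    rng = rng or np.random.default_rng(config.seed)
    G = np.asarray(genotypes, dtype=float)
    effects = np.asarray(effects, dtype=float)
    n, p = G.shape
    if effects.shape[0] != p or effects.shape[1] != config.K:
        raise ValueError("effects shape does not match genotypes/config")
    K, h2 = config.K, config.h2
    snp_sd = G.std(axis=0)
    polymorphic = snp_sd > 0
    # dosage-scale effect of one unit of standardised-scale effect
    scale = np.where(polymorphic, 1.0 / np.where(polymorphic, snp_sd, 1.0), 0.0)
    Z = np.where(polymorphic, (G - G.mean(axis=0)) * scale, 0.0)
    cts = np.empty((n, K))
    effects_out = np.zeros_like(effects)
    for k in range(K):
        if np.any(effects[:, k] != 0.0):
            u = np.where(polymorphic, effects[:, k], 0.0)
            g = Z @ u
            if g.var() == 0.0:
                raise ValueError(
                    f"heritability {h2} unattainable: no genetic variance in cell type {k}"
                )
            e = rng.normal(0.0, np.sqrt((1.0 - h2) / h2 * g.var()), size=n)
            c, meth = _calibrated_column(g, e, h2)
            sd = meth.std()
            cts[:, k] = meth / sd
            effects_out[:, k] = u * scale * c / sd
        else:
            cts[:, k] = rng.normal(0.0, 1.0, size=n)
    W = rng.dirichlet(config.dirichlet_alpha, size=n)
    eps = rng.normal(0.0, np.sqrt(config.bulk_noise_var), size=n)
    bulk = (W * cts).sum(axis=1) + eps
    m = int(round(config.cts_subset_frac * n))
    subset = np.sort(rng.choice(n, size=m, replace=False))
    causal = np.flatnonzero(np.any(effects_out != 0.0, axis=1))
    return SimulatedDataset(
        genotypes=G,
        true_effects=effects_out,
        cts_meth=cts,
        proportions=W,
        bulk=bulk,
        epsilon=eps,
        cts_subset_index=subset,
        causal_index=causal,
    )


def simulate_dataset(config: ScenarioConfig) -> SimulatedDataset:
    """Full locus simulation, reproducible from ``(config, config.seed)``."""
    rng = np.random.default_rng(config.seed)
    geno, mafs = simulate_genotypes(config, rng)
    effects, _ = simulate_effects(config, rng)
    data = simulate_cts_and_bulk(geno, effects, config, rng)
    data.mafs = mafs
    return data


def perturb_proportions(
    proportions: np.ndarray,
    target_mae: float,
    seed: int | np.random.Generator = 0,
) -> np.ndarray:
    """Noisy cell-type proportions with a calibrated mean absolute error.

    Adds half-normal noise (a zero-mean normal left-truncated at zero) to
    every entry and renormalises rows to sum to 1.  The noise scale is
    found by bisection so the realised MAE against the true proportions is
    within 10% of ``target_mae`` (the calibration stops at 1%).
    """
    W = np.asarray(proportions, dtype=float)
    if target_mae < 0:
        raise ValueError("target_mae must be nonnegative")
    if target_mae == 0.0:
        return W.copy()
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    z = np.abs(rng.standard_normal(W.shape))  # fixed draws; scale by sigma

    def realized(sigma: float) -> tuple[float, np.ndarray]:
        noisy = W + sigma * z
        noisy = noisy / noisy.sum(axis=1, keepdims=True)
        return float(np.mean(np.abs(noisy - W))), noisy

    lo, hi = 0.0, 1.0
    while realized(hi)[0] < target_mae:
        hi *= 2.0
        if hi > 1e4:
            raise RuntimeError("could not bracket the requested MAE")
    for _ in range(100):
        mid = 0.5 * (lo + hi)
        mae, noisy = realized(mid)
        if abs(mae - target_mae) <= 0.01 * target_mae:
            return noisy
        if mae < target_mae:
            lo = mid
        else:
            hi = mid
    return realized(0.5 * (lo + hi))[1]
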