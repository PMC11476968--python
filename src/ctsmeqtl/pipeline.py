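"""Genome-scale cis-meQTL scan and replication statistics.

SNPs are paired with CpGs within a closed +/- window (default 500 kb,
boundary inclusive, 1-based positions, same genome build assumed for both
tables).  Each pair is fitted with the hierarchical interaction model and
thresholded; pairs are independent work units, so any execution order gives
identical results.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .design import build_interaction_design
from .model import FitResult, HyperParams, PriorSpec, fit_hierarchical_interaction

logger = logging.getLogger(__name__)

DEFAULT_WINDOW = 500_000
MISSING_CAP = 0.05

RESULT_COLUMNS = [
    "cpg", "snp", "chr", "cpg_pos", "snp_pos",
    "celltype", "beta", "se", "p", "converged",
]


def cis_pairs(
    snp_positions: pd.DataFrame,
    cpg_positions: pd.DataFrame,
    window: int = DEFAULT_WINDOW,
) -> pd.DataFrame:
    """All same-chromosome SNP-CpG pairs with ``|pos_snp - pos_cpg| <= window``.

    Both tables need columns ``id``, ``chrom``, ``pos`` (1-based).  The
    window is closed: a SNP exactly ``window`` bases away is included.
    """
    for name, tab in (("snp", snp_positions), ("cpg", cpg_positions)):
        missing = {"id", "chrom", "pos"} - set(tab.columns)
        if missing:
            raise ValueError(f"{name} table lacks columns {sorted(missing)}")
    if snp_positions["id"].duplicated().any():
        dup = snp_positions.loc[snp_positions["id"].duplicated(), "id"].tolist()
        raise ValueError(f"duplicated SNP ids: {dup[:5]}")
    merged = cpg_positions.merge(
        snp_positions, on="chrom", suffixes=("_cpg", "_snp")
    )
    keep = (merged["pos_snp"] - merged["pos_cpg"]).abs() <= window
    out = merged.loc[keep, ["id_cpg", "id_snp", "chrom", "pos_cpg", "pos_snp"]]
    out = out.rename(columns={"id_cpg": "cpg", "id_snp": "snp"})
    return out.reset_index(drop=True)


def bonferroni_threshold(n_pairs: int, n_celltypes: int, alpha: float = 0.05) -> float:
    """Family-wise threshold ``alpha / n_pairs / n_celltypes``."""
    if n_pairs < 1 or n_celltypes < 1 or alpha <= 0:
        raise ValueError("inputs must be positive")
    return alpha / n_pairs / n_celltypes


def impute_dosages(dosages: np.ndarray, missing_cap: float = MISSING_CAP) -> np.ndarray:
    """Mean-impute missing dosages per SNP; reject SNPs above the missingness cap."""
    d = np.asarray(dosages, dtype=float).copy()
    miss = ~np.isfinite(d)
    if miss.any():
        rate = miss.mean()
        if rate > missing_cap:
            raise ValueError(f"missingness {rate:.1%} exceeds cap {missing_cap:.0%}")
        d[miss] = d[~miss].mean() if (~miss).any() else 0.0
    return d


def run_scan(
    bulk: pd.DataFrame,
    proportions: pd.DataFrame,
    genotypes: pd.DataFrame,
    snp_positions: pd.DataFrame,
    cpg_positions: pd.DataFrame,
    covariates: pd.DataFrame | None = None,
    priors: dict[tuple[str, str], PriorSpec] | None = None,
    hyper: HyperParams | None = None,
    window: int = DEFAULT_WINDOW,
    alpha: float = 0.05,
    threshold: float | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Fit the hierarchical model for every cis pair.

    Parameters
    ----------
    bulk : CpG x sample methylation (M-values), index = CpG ids.
    proportions : sample x cell type, index = sample ids.
    genotypes : SNP x sample dosage matrix, index = SNP ids; NaN dosages are
        mean-imputed per SNP up to a 5% missingness cap.
    priors : optional per-pair priors keyed ``(cpg, snp)``; pairs without an
        entry use the uninformative prior.
    threshold : significance cutoff; defaults to the Bonferroni threshold
        over the tested pairs and cell types.

    Returns
    -------
    (results, significant) : full PairResult table and the thresholded subset.
    """
    samples = proportions.index
    samples = samples.intersection(bulk.columns).intersection(genotypes.columns)
    if covariates is not None:
        samples = samples.intersection(covariates.index)
    samples = sorted(samples)
    logger.info("scan over %d shared samples", len(samples))
    W = proportions.loc[samples]
    K = W.shape[1]
    celltypes = list(W.columns)
    cov = covariates.loc[samples].to_numpy() if covariates is not None else None

    pairs = cis_pairs(snp_positions, cpg_positions, window=window)
    pairs = pairs[pairs["cpg"].isin(bulk.index) & pairs["snp"].isin(genotypes.index)]
    if threshold is None:
        threshold = bonferroni_threshold(max(len(pairs), 1), K, alpha)

    rows: list[dict] = []
    for pair in pairs.itertuples(index=False):
        y = bulk.loc[pair.cpg, samples].to_numpy(dtype=float)
        g = genotypes.loc[pair.snp, samples].to_numpy(dtype=float)
        prior = (priors or {}).get((pair.cpg, pair.snp))
        try:
            g = impute_dosages(g)
            design = build_interaction_design(
                y, W.to_numpy(), g, covariates=cov, celltype_names=celltypes
            )
            fit: FitResult | None = fit_hierarchical_interaction(
                design, prior=prior, hyper=hyper
            )
        except Exception as err:  # per-pair failures never abort the scan
            logger.warning("fit failed for %s-%s: %s", pair.cpg, pair.snp, err)
            fit = None
        for k in range(K):
            rows.append(
                {
                    "cpg": pair.cpg,
                    "snp": pair.snp,
                    "chr": pair.chrom,
                    "cpg_pos": pair.pos_cpg,
                    "snp_pos": pair.pos_snp,
                    "celltype": celltypes[k],
                    "beta": fit.cts_effects[k] if fit else np.nan,
                    "se": fit.cts_se[k] if fit else np.nan,
                    "p": fit.cts_p[k] if fit else np.nan,
                    "converged": bool(fit.converged) if fit else False,
                }
            )
    results = pd.DataFrame(rows, columns=RESULT_COLUMNS)
    significant = results[results["p"] < threshold].reset_index(drop=True)
    return results, significant


def replication_stats(
    discovery: pd.DataFrame,
    replication: pd.DataFrame,
    p_threshold: float = 0.05,
) -> dict[str, float]:
    """Replication summary over pairs shared with an external result table.

    Both tables need columns ``snp``, ``cpg``, ``celltype``, ``beta``, ``p``;
    the join is on (snp, cpg, celltype).  A pair replicates when the
    replication p-value is below ``p_threshold`` and the effect signs agree.
    All rates are percentages; with no shared pairs every rate is NaN.
    """
    keys = ["snp", "cpg", "celltype"]
    merged = discovery.merge(replication, on=keys, suffixes=("_disc", "_rep"))
    n = len(merged)
    if n == 0:
        return {
            "n_shared": 0,
            "pct_consistent_sign": np.nan,
            "pct_replicated": np.nan,
            "pct_significant_consistent": np.nan,
            "effect_correlation_replicated": np.nan,
        }
    same_sign = np.sign(merged["beta_disc"]) == np.sign(merged["beta_rep"])
    rep_sig = merged["p_rep"] < p_threshold
    replicated = same_sign & rep_sig
    n_sig = int(rep_sig.sum())
    bd = merged.loc[replicated, "beta_disc"].to_numpy()
    br = merged.loc[replicated, "beta_rep"].to_numpy()
    if replicated.sum() >= 2 and bd.std() > 0 and br.std() > 0:
        corr = float(np.corrcoef(bd, br)[0, 1])
    else:
        corr = np.nan
    return {
        "n_shared": n,
        "pct_consistent_sign": 100.0 * same_sign.mean(),
        "pct_replicated": 100.0 * replicated.mean(),
        "pct_significant_consistent": (
            100.0 * float((replicated & rep_sig).sum() / n_sig) if n_sig else np.nan
        ),
        "effect_correlation_replicated": corr,
    }
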