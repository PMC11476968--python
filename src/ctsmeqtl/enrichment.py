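"""Downstream enrichment statistics for identified meQTLs.

Two statistics are provided: Fisher's exact test on the 2x2 table of
meQTL membership against functional-region membership, and the cell-type
colocalization enrichment score (ratio of the cell type's share among
colocalized meQTL clumps to its share among all clumps) with a one-sided
continuity-corrected two-proportion test.
"""

from __future__ import annotations

import numpy as np
from scipy import stats


def fisher_enrichment_2x2(mr: int, m: int, r: int, t: int):
    """Fisher's exact test of meQTL enrichment in a functional region.

    Parameters
    ----------
    mr : meQTLs inside the region.
    m : total meQTLs.
    r : variants inside the region.
    t : total variants tested.

    The table is ``[[mr, r - mr], [m - mr, t - r - (m - mr)]]``.  The
    two-sided p sums hypergeometric probabilities not exceeding the
    observed table's.  The odds ratio is the sample OR with a Haldane 0.5
    correction when any cell is zero, and the 95% CI is Wald on the log-OR.

    Returns
    -------
    (odds_ratio, (ci_low, ci_high), p_value)
    """
    cells = np.array([mr, r - mr, m - mr, t - r - (m - mr)], dtype=float)
    if np.any(cells < 0) or mr > min(m, r) or m > t or r > t:
        raise ValueError("inconsistent contingency margins")
    table = cells.reshape(2, 2)
    _, p = stats.fisher_exact(table, alternative="two-sided")
    c = cells + 0.5 if np.any(cells == 0) else cells
    oddsr = (c[0] * c[3]) / (c[1] * c[2])
    se = np.sqrt(np.sum(1.0 / c))
    log_or = np.log(oddsr)
    ci = (float(np.exp(log_or - 1.96 * se)), float(np.exp(log_or + 1.96 * se)))
    return float(oddsr), ci, float(p)


def proportions_ztest_corrected(x1: int, n1: int, x2: int, n2: int) -> tuple[float, float]:
    """One-sided (greater) two-proportion test with continuity correction.

    Yates-corrected chi-square statistic, signed by the direction of the
    difference; the one-sided p-value uses the signed square root against a
    standard normal.  Matches R's ``prop.test(alternative = "greater")``.
    """
    if min(n1, n2) <= 0 or not (0 <= x1 <= n1 and 0 <= x2 <= n2):
        raise ValueError("invalid counts")
    x = np.array([x1, x2], dtype=float)
    n = np.array([n1, n2], dtype=float)
    p_hat = x / n
    delta = p_hat[0] - p_hat[1]
    yates = min(0.5, abs(delta) / np.sum(1.0 / n))
    p_pool = x.sum() / n.sum()
    E = np.outer([p_pool, 1 - p_pool], n).T  # expected counts
    O = np.column_stack([x, n - x])
    chi2 = float(np.sum((np.abs(O - E) - yates) ** 2 / E))
    z = np.sign(delta) * np.sqrt(chi2)
    return float(z), float(stats.norm.sf(z))


def coloc_enrichment(
    coloc_count_k: int, coloc_total: int, clump_count_k: int, clump_total: int
):
    """Cell-type enrichment of meQTL-GWAS colocalizations.

    The score divides the cell type's share of colocalized clumps by its
    share of all meQTL clumps; the p-value tests share equality (one-sided,
    greater) with continuity correction.  A zero clump count makes the
    score undefined (NaN).

    Returns ``(score, p_value)``.
    """
    if min(coloc_total, clump_total) <= 0 or min(coloc_count_k, clump_count_k) < 0:
        raise ValueError("totals must be positive and counts nonnegative")
    if clump_count_k == 0:
        return np.nan, np.nan
    score = (coloc_count_k / coloc_total) / (clump_count_k / clump_total)
    _, p = proportions_ztest_corrected(
        coloc_count_k, coloc_total, clump_count_k, clump_total
    )
    return float(score), float(p)


def coloc_significance_threshold(
    n_traits: int = 54, n_celltypes: int = 6, alpha: float = 0.05
) -> float:
    """Bonferroni threshold across traits and cell types (0.05/54/6 = 1.5e-4)."""
    return alpha / n_traits / n_celltypes
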