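"""Metrics for method comparison on simulated loci.

Point estimation is summarised by the Pearson correlation and mean squared
error between estimated and true effect matrices; detection by power and
false discovery proportion after Benjamini-Hochberg selection within each
cell type, pooled over cell types:

    power = # identified true signals (all cell types) / # true signals
    FDR   = # identified false signals (all cell types) / # identified

Replicate summaries use medians.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from statsmodels.stats.multitest import multipletests


def effect_metrics(estimated, truth, pooled: bool = True):
    """Correlation and MSE between effect matrices.

    With ``pooled=True`` (default) entries are flattened across cell types
    into a single pair of vectors; otherwise per-cell-type columns are
    returned.  A zero-variance estimate vector yields ``nan`` correlation.
    """
    est = np.asarray(estimated, dtype=float)
    tru = np.asarray(truth, dtype=float)
    if est.shape != tru.shape:
        raise ValueError("estimated and truth must have the same shape")

    def one(e, t):
        mse = float(np.mean((e - t) ** 2))
        if e.std() == 0.0 or t.std() == 0.0:
            return np.nan, mse
        return float(np.corrcoef(e, t)[0, 1]), mse

    if pooled:
        return one(est.ravel(), tru.ravel())
    out = [one(est[:, k], tru[:, k]) for k in range(est.shape[1])]
    corr, mse = zip(*out)
    return np.asarray(corr), np.asarray(mse)


def detection_metrics(p_values, truth_nonzero, fdr_level: float = 0.05):
    """BH selection within each cell type; pooled power and FDR.

    Returns ``(power, fdr, selected)`` where ``selected`` is the boolean
    selection matrix.  FDR is 0 by convention when nothing is selected.
    """
    p = np.asarray(p_values, dtype=float)
    truth = np.asarray(truth_nonzero, dtype=bool)
    if p.shape != truth.shape:
        raise ValueError("p_values and truth_nonzero must have the same shape")
    if not 0 < fdr_level < 1:
        raise ValueError("fdr_level must lie in (0, 1)")
    if p.ndim == 1:
        p = p[:, None]
        truth = truth[:, None]
    selected = np.zeros_like(truth)
    for k in range(p.shape[1]):
        selected[:, k] = multipletests(p[:, k], alpha=fdr_level, method="fdr_bh")[0]
    n_true = int(truth.sum())
    n_sel = int(selected.sum())
    power = float((selected & truth).sum() / n_true) if n_true else np.nan
    fdr = float((selected & ~truth).sum() / n_sel) if n_sel else 0.0
    return power, fdr, selected


def summarize_replicates(per_replicate_metrics) -> dict[str, float]:
    """Elementwise median over replicate metric dicts (midpoint for even counts)."""
    if len(per_replicate_metrics) == 0:
        raise ValueError("need at least one replicate")
    df = pd.DataFrame(list(per_replicate_metrics))
    return df.median().to_dict()
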