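"""Interaction design matrices for cell-type-specific QTL models.

The bulk methylation level of a mixed-tissue sample is modelled as a
proportion-weighted combination of cell-type signals.  A genotype effect that
is specific to cell type ``k`` manifests in bulk as an interaction between the
genotype dosage ``G`` and the cell-type proportion ``W_k``:

    M = sum_c gamma_c X_c + sum_k alpha_k W_k + sum_k beta_k (W_k * G) + eps

(the *cell-means* form, no intercept).  Because proportions sum to one, the
model can equivalently be written with an intercept, a main genotype effect
and K-1 interaction contrasts relative to a reference cell type (the
*reference-cell* form); a linear back-map recovers the K per-cell-type
effects from either parameterisation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

#: accepted values for the ``form`` argument
FORMS = ("no-intercept", "reference-cell")

PROPORTION_TOL = 1e-6


@dataclass
class InteractionDesign:
    """Response and design matrix for one CpG-SNP pair.

    Columns are ordered covariates, proportion (or intercept) columns, then
    the K genotype-proportion columns whose coefficients are the cell-type
    -specific effects of interest.  ``cts_map`` is the K x J linear map from
    the full coefficient vector to per-cell-type effects on the cell-means
    scale, valid for either parameterisation.
    """

    response: np.ndarray
    design: np.ndarray
    n_covariates: int
    n_celltypes: int
    form: str
    column_labels: list[str]
    cts_map: np.ndarray
    constant_genotype: bool = False
    celltype_names: list[str] = field(default_factory=list)

    @property
    def n_samples(self) -> int:
        return self.design.shape[0]

    @property
    def n_coef(self) -> int:
        return self.design.shape[1]

    def __post_init__(self) -> None:
        if self.design.ndim != 2:
            raise ValueError("design must be 2-D")
        if self.response.shape[0] != self.design.shape[0]:
            raise ValueError("response/design sample mismatch")


def _as_2d(a, n: int, name: str) -> np.ndarray:
    arr = np.asarray(a, dtype=float)
    if arr.ndim == 1:
        arr = arr[:, None]
    if arr.shape[0] != n:
        raise ValueError(f"{name} has {arr.shape[0]} rows, expected {n}")
    return arr


def build_interaction_design(
    bulk_meth,
    proportions,
    genotype,
    covariates=None,
    form: str = "no-intercept",
    celltype_names: list[str] | None = None,
) -> InteractionDesign:
    """Assemble the interaction design for one CpG-SNP pair.

    Parameters
    ----------
    bulk_meth : array-like, shape (n,)
        Bulk methylation at the CpG (M-values recommended).
    proportions : array-like, shape (n, K)
        Cell-type proportions; rows must sum to 1 within ``1e-6`` and are
        renormalised to sum exactly to 1.
    genotype : array-like, shape (n,)
        Alternative-allele dosages in [0, 2].
    covariates : array-like, shape (n, C), optional
    form : {"no-intercept", "reference-cell"}
        Parameterisation; the last cell type is the reference in the
        reference-cell form.

    Returns
    -------
    InteractionDesign
    """
    if form not in FORMS:
        raise ValueError(f"form must be one of {FORMS}, got {form!r}")
    y = np.asarray(bulk_meth, dtype=float).ravel()
    n = y.shape[0]
    W = _as_2d(proportions, n, "proportions")
    g = np.asarray(genotype, dtype=float).ravel()
    if g.shape[0] != n:
        raise ValueError("genotype length mismatch")
    if np.any(np.isnan(y)) or np.any(np.isnan(W)) or np.any(np.isnan(g)):
        raise ValueError("NaN in model inputs")
    if g.min() < -1e-9 or g.max() > 2 + 1e-9:
        raise ValueError("genotype dosages must lie in [0, 2]")
    K = W.shape[1]
    if np.any(W < -1e-9):
        raise ValueError("negative cell-type proportion")
    rowsum = W.sum(axis=1)
    if np.any(np.abs(rowsum - 1.0) > PROPORTION_TOL):
        worst = np.abs(rowsum - 1.0).max()
        raise ValueError(
            f"proportion rows must sum to 1 within {PROPORTION_TOL}; worst deviation {worst:.3g}"
        )
    W = W / rowsum[:, None]

    if covariates is None:
        X_c = np.empty((n, 0))
    else:
        X_c = _as_2d(covariates, n, "covariates")
    C = X_c.shape[1]
    J = C + 2 * K
    if n < J + 2:
        raise ValueError(f"need at least J + 2 = {J + 2} samples, got {n}")

    names = list(celltype_names) if celltype_names else [f"ct{k + 1}" for k in range(K)]
    if len(names) != K:
        raise ValueError("celltype_names length mismatch")
    cov_labels = [f"cov{c + 1}" for c in range(C)]
    constant_genotype = bool(np.ptp(g) == 0.0)

    if form == "no-intercept":
        design = np.hstack([X_c, W, W * g[:, None]])
        labels = cov_labels + [f"W[{nm}]" for nm in names] + [f"W[{nm}]:G" for nm in names]
        cts_map = np.zeros((K, J))
        cts_map[:, C + K :] = np.eye(K)
    else:
        # intercept absorbs the reference proportion; G absorbs the
        # reference-cell effect: beta_k = beta~_0 + beta~_k, beta_K = beta~_0
        design = np.hstack(
            [X_c, np.ones((n, 1)), W[:, : K - 1], g[:, None], W[:, : K - 1] * g[:, None]]
        )
        labels = (
            cov_labels
            + ["intercept"]
            + [f"W[{nm}]" for nm in names[: K - 1]]
            + ["G"]
            + [f"W[{nm}]:G" for nm in names[: K - 1]]
        )
        cts_map = np.zeros((K, J))
        g_col = C + K  # position of the main genotype column
        cts_map[:, g_col] = 1.0
        for k in range(K - 1):
            cts_map[k, g_col + 1 + k] = 1.0

    return InteractionDesign(
        response=y,
        design=design,
        n_covariates=C,
        n_celltypes=K,
        form=form,
        column_labels=labels,
        cts_map=cts_map,
        constant_genotype=constant_genotype,
        celltype_names=names,
    )


def beta_to_mvalue(beta_values, eps: float = 1e-6) -> np.ndarray:
    """Logit2 transform of methylation beta-values: ``log2(b / (1 - b))``.

    Values are clipped to ``[eps, 1 - eps]`` to keep the transform finite.
    """
    b = np.clip(np.asarray(beta_values, dtype=float), eps, 1.0 - eps)
    return np.log2(b / (1.0 - b))
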