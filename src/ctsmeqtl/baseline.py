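"""Basic interaction model: the same design fitted by ordinary least squares.

This is the unpenalised comparator (in the spirit of CellDMC-style
interaction tests): classical OLS with t-based Wald inference on n - J
residual degrees of freedom, in contrast to the hierarchical model's
large-sample normal reference.
"""

from __future__ import annotations

import numpy as np
import statsmodels.api as sm
from scipy import stats
from sklearn.base import BaseEstimator, RegressorMixin

from .design import InteractionDesign
from .model import FitResult


class OLSInteractionModel(RegressorMixin, BaseEstimator):
    """OLS fit of the cell-type interaction design.

    Attributes mirror :class:`BayesianInteractionModel`: ``coef_``,
    ``coef_var_``, ``cts_effects_``, ``cts_se_``, ``cts_p_`` (t reference,
    ``n - J`` degrees of freedom), ``phi_`` (residual variance, ``n - J``
    divisor).
    """

    def __init__(self, n_celltypes: int | None = None):
        self.n_celltypes = n_celltypes

    def fit(self, X, y=None):
        if isinstance(X, InteractionDesign):
            design = X
            Xd, yd = design.design, design.response
            cts_map = design.cts_map
        else:
            Xd = np.asarray(X, dtype=float)
            yd = np.asarray(y, dtype=float).ravel()
            if self.n_celltypes is None:
                raise ValueError("n_celltypes must be set to fit a bare design matrix")
            K = int(self.n_celltypes)
            cts_map = np.zeros((K, Xd.shape[1]))
            cts_map[:, Xd.shape[1] - K :] = np.eye(K)
            design = None
        n, J = Xd.shape
        if n <= J:
            raise ValueError(f"OLS requires n > J (n={n}, J={J})")
        rank = np.linalg.matrix_rank(Xd)
        if rank < J:
            # name the offending columns for the caller
            labels = design.column_labels if design is not None else [
                f"x{j}" for j in range(J)
            ]
            _, R = np.linalg.qr(Xd)
            dep = [labels[j] for j in range(J) if abs(R[j, j]) < 1e-8 * abs(R).max()]
            raise np.linalg.LinAlgError(
                f"rank-deficient design (rank {rank} < {J}); collinear columns: {dep}"
            )
        res = sm.OLS(yd, Xd).fit()
        dof = n - J
        theta = res.params
        theta_var = np.asarray(res.cov_params())
        cts = cts_map @ theta
        cts_var = cts_map @ theta_var @ cts_map.T
        cts_se = np.sqrt(np.clip(np.diag(cts_var), 0.0, None))
        with np.errstate(divide="ignore", invalid="ignore"):
            t = np.where(cts_se > 0, cts / cts_se, np.inf * np.sign(cts))
        cts_p = np.clip(2.0 * stats.t.sf(np.abs(t), dof), 0.0, 1.0)

        self.design_ = design
        self.coef_ = theta
        self.coef_var_ = theta_var
        self.cts_effects_ = cts
        self.cts_se_ = cts_se
        self.cts_p_ = cts_p
        self.phi_ = float(res.mse_resid)
        self.dof_ = dof
        self.result_ = FitResult(
            theta=theta,
            theta_var=theta_var,
            cts_effects=cts,
            cts_se=cts_se,
            cts_p=cts_p,
            phi=self.phi_,
            n_iter=1,
            converged=True,
            column_labels=(design.column_labels if design is not None else []),
        )
        return self

    def predict(self, X):
        Xd = X.design if isinstance(X, InteractionDesign) else np.asarray(X, dtype=float)
        return Xd @ self.coef_


def fit_ols_interaction(design: InteractionDesign) -> FitResult:
    """Functional entry point for the OLS comparator."""
    return OLSInteractionModel().fit(design).result_
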