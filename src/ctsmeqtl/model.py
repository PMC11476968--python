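"""Hierarchical Bayesian interaction model fitted by EM-IWLS.

The cell-type-specific genotype effects ``beta_k`` carry a Bayesian adaptive
lasso prior: conditional on a scale ``tau_k^2`` the coefficient is normal,
``tau_k^2 | s_k`` is exponential with rate ``s_k^2 / 2`` and ``s_k`` has a
``Gamma(a, b_k)`` hyper-prior.  Marginally each ``beta_k`` follows a
double-exponential (Laplace) distribution centred at the prior mean
``mu_k``, so the posterior mode performs coefficient-specific soft
shrinkage toward ``mu_k``.

Fitting treats ``(s_k, tau_k^2)`` as missing data.  The E-step replaces them
by their conditional posterior expectations

    E[s_k | beta_k]       = (a + 1) / (b_k + |beta_k - mu_k|)
    E[1/tau_k^2 | s_k, .] = s_k / |beta_k - mu_k|

(Gamma and inverse-Gaussian means).  The M-step augments the n data rows
with J pseudo-observations encoding the priors and solves a single weighted
least-squares problem; iterating to convergence yields the posterior mode
and a Wald covariance ``(X*' S*^-1 X*)^-1 phi``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats
from sklearn.base import BaseEstimator, RegressorMixin

from .design import InteractionDesign, build_interaction_design
from .priors import HyperParams, PriorSpec, uninformative_prior

PHI_FLOOR = 1e-12
COND_LIMIT = 1e12


@dataclass
class LatentState:
    """E-step expectations: shrinkage scales, precisions, residual variance."""

    s: np.ndarray
    inv_tau2: np.ndarray
    phi: float

    def __post_init__(self) -> None:
        self.s = np.asarray(self.s, dtype=float)
        self.inv_tau2 = np.asarray(self.inv_tau2, dtype=float)
        if not (
            np.all(np.isfinite(self.s))
            and np.all(self.s > 0)
            and np.all(np.isfinite(self.inv_tau2))
            and np.all(self.inv_tau2 > 0)
            and np.isfinite(self.phi)
            and self.phi > 0
        ):
            raise ValueError("latent state entries must be positive and finite")


@dataclass
class FitResult:
    """Coefficients, covariance and per-cell-type Wald inference."""

    theta: np.ndarray
    theta_var: np.ndarray
    cts_effects: np.ndarray
    cts_se: np.ndarray
    cts_p: np.ndarray
    phi: float
    n_iter: int
    converged: bool
    trace: np.ndarray = field(default_factory=lambda: np.empty(0))
    column_labels: list[str] = field(default_factory=list)


def estep_expectations(
    beta, prior: PriorSpec, hyper: HyperParams, phi: float = 1.0
) -> LatentState:
    """Conditional posterior means of the latent shrinkage quantities.

    ``|beta_k - mu_k|`` is floored at ``hyper.beta_floor`` so both
    expectations stay finite when an estimate sits exactly on its prior mean.
    """
    beta = np.asarray(beta, dtype=float).ravel()
    if not np.all(np.isfinite(beta)):
        raise ValueError("beta must be finite")
    K = prior.n_celltypes
    if beta.shape[0] != K:
        raise ValueError(f"beta must have length {K}")
    b = hyper.rates(K)
    dev = np.maximum(np.abs(beta - prior.mu), hyper.beta_floor)
    s = (hyper.a + 1.0) / (b + dev)
    inv_tau2 = s / dev
    return LatentState(s=s, inv_tau2=inv_tau2, phi=float(phi))


def _prior_precision(design: InteractionDesign, prior: PriorSpec, state: LatentState) -> np.ndarray:
    """J x J precision of the coefficient prior (inverse of blockdiag(S22, S33))."""
    J, K = design.n_coef, design.n_celltypes
    P = np.zeros((J, J))
    idx = np.arange(J - K)
    P[idx, idx] = 1.0 / prior.nuisance_variance
    d_inv = np.sqrt(state.inv_tau2)
    P[J - K :, J - K :] = prior.rho_inv * np.outer(d_inv, d_inv)
    return P


def _prior_mean(design: InteractionDesign, prior: PriorSpec) -> np.ndarray:
    J, K = design.n_coef, design.n_celltypes
    m = np.zeros(J)
    if prior.nuisance_mean is not None:
        m[: J - K] = prior.nuisance_mean
    m[J - K :] = prior.mu
    return m


@dataclass
class AugmentedSystem:
    """Data rows stacked over J prior pseudo-observations.

    ``y_star = [M, 0, mu]``, ``X_star = [X; I_J]``.  The covariance of
    ``y_star`` is ``phi * S*`` whose prior blocks carry a ``1/phi`` factor,
    so the pseudo-observation weights ``phi * P`` are free of ``phi`` only
    through the data rows; ``prior_precision`` already includes the factor.
    """

    y_star: np.ndarray
    X_star: np.ndarray
    n_data: int
    prior_precision: np.ndarray  # phi * P, acting on the J prior rows
    prior_mean: np.ndarray


def assemble_augmented_system(
    design: InteractionDesign, prior: PriorSpec, state: LatentState
) -> AugmentedSystem:
    """Encode the priors as pseudo-observations under the data rows."""
    J = design.n_coef
    m = _prior_mean(design, prior)
    P = _prior_precision(design, prior, state)
    if not np.all(np.isfinite(P)):
        raise np.linalg.LinAlgError("non-finite prior precision (singular S33 block)")
    y_star = np.concatenate([design.response, m])
    X_star = np.vstack([design.design, np.eye(J)])
    return AugmentedSystem(
        y_star=y_star,
        X_star=X_star,
        n_data=design.n_samples,
        prior_precision=state.phi * P,
        prior_mean=m,
    )


def _guarded_solve(A: np.ndarray, rhs: np.ndarray) -> np.ndarray:
    """Solve A theta = rhs with a condition-number guard.

    Conditioning is measured after symmetric diagonal equilibration: prior
    precisions legitimately span many orders of magnitude (a coefficient
    pinned to its prior mean has a near-infinite precision), which inflates
    the raw condition number without harming the solve; genuine
    collinearity survives equilibration.
    """
    d = np.sqrt(np.clip(np.diag(A), 1e-300, None))
    As = A / np.outer(d, d)
    cond = np.linalg.cond(As)
    if not np.isfinite(cond) or cond > COND_LIMIT:
        raise np.linalg.LinAlgError(
            f"singular normal equations (equilibrated condition number {cond:.3g})"
        )
    return np.linalg.solve(As, rhs / d) / d


def mstep_update(system: AugmentedSystem) -> tuple[np.ndarray, float]:
    """Weighted least-squares update of (theta, phi) on the augmented system.

    ``phi`` uses divisor ``n`` (the data sample count) and is floored at
    ``1e-12`` so downstream variances stay defined for interpolating fits.
    """
    n = system.n_data
    Xd, Xp = system.X_star[:n], system.X_star[n:]
    yd, yp = system.y_star[:n], system.y_star[n:]
    A = Xd.T @ Xd + Xp.T @ (system.prior_precision @ Xp)
    rhs = Xd.T @ yd + Xp.T @ (system.prior_precision @ yp)
    theta = _guarded_solve(A, rhs)
    rd = yd - Xd @ theta
    rp = yp - Xp @ theta
    phi = (rd @ rd + rp @ (system.prior_precision @ rp)) / n
    return theta, max(float(phi), PHI_FLOOR)


def _ols_init(X: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, float]:
    """OLS starting values with a tiny ridge fallback for singular designs."""
    G = X.T @ X
    try:
        theta = np.linalg.solve(G, X.T @ y)
        if not np.all(np.isfinite(theta)):
            raise np.linalg.LinAlgError
    except np.linalg.LinAlgError:
        theta = np.linalg.solve(G + 1e-6 * np.eye(G.shape[0]), X.T @ y)
    resid = y - X @ theta
    phi0 = max(float(resid @ resid) / X.shape[0], PHI_FLOOR)
    return theta, phi0


class BayesianInteractionModel(RegressorMixin, BaseEstimator):
    """Cell-type-specific QTL effects by hierarchical Bayesian shrinkage.

    Parameters
    ----------
    a, b : Gamma hyper-prior shape and rate(s) for the shrinkage scales;
        ``b`` may be a scalar or one rate per cell type.
    prior : PriorSpec, optional
        Informative prior means/correlation from sorted-cell data.  When
        omitted, a zero-mean uncorrelated prior is used.
    delta, max_iter : EM-IWLS convergence tolerance on ``max |d theta|`` and
        iteration cap.
    beta_floor : floor on ``|beta_k - mu_k|`` in E-step denominators.
    nuisance_variance : fixed diffuse prior variance for non-interaction
        coefficients (overridden by ``prior.nuisance_variance`` if a prior
        is given).
    n_celltypes : required only when ``fit`` receives a bare matrix whose
        last K columns are the genotype-proportion interactions.

    Attributes
    ----------
    coef_ : full coefficient vector theta = [gamma, alpha, beta].
    coef_var_ : Wald covariance of ``coef_``.
    cts_effects_, cts_se_, cts_p_ : per-cell-type effects on the cell-means
        scale with standard errors and two-sided normal p-values.
    phi_, n_iter_, converged_, trace_ : residual variance and EM record.
    """

    def __init__(
        self,
        a: float = 0.5,
        b=0.2,
        prior: PriorSpec | None = None,
        delta: float = 1e-5,
        max_iter: int = 500,
        beta_floor: float = 1e-8,
        nuisance_variance: float = 1e8,
        n_celltypes: int | None = None,
    ):
        self.a = a
        self.b = b
        self.prior = prior
        self.delta = delta
        self.max_iter = max_iter
        self.beta_floor = beta_floor
        self.nuisance_variance = nuisance_variance
        self.n_celltypes = n_celltypes

    def _coerce_design(self, X, y) -> InteractionDesign:
        if isinstance(X, InteractionDesign):
            return X
        Xa = np.asarray(X, dtype=float)
        if y is None:
            raise ValueError("y is required when X is a bare design matrix")
        if self.n_celltypes is None:
            raise ValueError("n_celltypes must be set to fit a bare design matrix")
        K = int(self.n_celltypes)
        J = Xa.shape[1]
        cts_map = np.zeros((K, J))
        cts_map[:, J - K :] = np.eye(K)
        return InteractionDesign(
            response=np.asarray(y, dtype=float).ravel(),
            design=Xa,
            n_covariates=J - 2 * K,
            n_celltypes=K,
            form="no-intercept",
            column_labels=[f"x{j}" for j in range(J)],
            cts_map=cts_map,
        )

    def fit(self, X, y=None):
        design = self._coerce_design(X, y)
        Xd, yd = design.design, design.response
        if not (np.all(np.isfinite(Xd)) and np.all(np.isfinite(yd))):
            raise ValueError("NaN or infinite values in model inputs")
        n, J = Xd.shape
        K = design.n_celltypes
        if n <= J:
            warnings.warn(f"n = {n} <= J = {J}: fit is prior-dominated", stacklevel=2)
        prior = self.prior if self.prior is not None else uninformative_prior(
            K, nuisance_variance=self.nuisance_variance
        )
        if prior.n_celltypes != K:
            raise ValueError("prior dimension does not match the design")
        hyper = HyperParams(
            a=self.a, b=self.b, delta=self.delta,
            max_iter=self.max_iter, beta_floor=self.beta_floor,
        )

        # sufficient statistics; the design never changes across iterations
        Gxx = Xd.T @ Xd
        Gxy = Xd.T @ yd
        yy = float(yd @ yd)
        m = _prior_mean(design, prior)
        sel = slice(J - K, J)  # interaction coefficients within theta

        theta, phi = _ols_init(Xd, yd)
        trace = []
        converged = False
        n_iter = 0
        A = Gxx  # overwritten each iteration; kept for the final covariance
        for n_iter in range(1, hyper.max_iter + 1):
            state = estep_expectations(theta[sel], prior, hyper, phi=phi)
            P = _prior_precision(design, prior, state)
            A = Gxx + phi * P
            theta_new = _guarded_solve(A, Gxy + phi * (P @ m))
            rss = max(yy - 2.0 * theta_new @ Gxy + theta_new @ (Gxx @ theta_new), 0.0)
            dm = theta_new - m
            phi_new = max((rss + phi * (dm @ (P @ dm))) / n, PHI_FLOOR)
            step = float(np.max(np.abs(theta_new - theta)))
            trace.append(step)
            theta, phi = theta_new, phi_new
            if step < hyper.delta:
                converged = True
                break

        d = np.sqrt(np.clip(np.diag(A), 1e-300, None))
        theta_var = np.linalg.inv(A / np.outer(d, d)) / np.outer(d, d) * phi
        cts = design.cts_map @ theta
        cts_var = design.cts_map @ theta_var @ design.cts_map.T
        cts_se = np.sqrt(np.clip(np.diag(cts_var), 0.0, None))
        with np.errstate(divide="ignore", invalid="ignore"):
            z = np.where(cts_se > 0, cts / cts_se, np.inf * np.sign(cts))
        cts_p = 2.0 * stats.norm.sf(np.abs(z))

        self.design_ = design
        self.coef_ = theta
        self.coef_var_ = theta_var
        self.cts_effects_ = cts
        self.cts_se_ = cts_se
        self.cts_p_ = np.clip(cts_p, 0.0, 1.0)
        self.phi_ = phi
        self.n_iter_ = n_iter
        self.converged_ = converged
        self.trace_ = np.asarray(trace)
        self.result_ = FitResult(
            theta=theta,
            theta_var=theta_var,
            cts_effects=cts,
            cts_se=cts_se,
            cts_p=self.cts_p_,
            phi=phi,
            n_iter=n_iter,
            converged=converged,
            trace=self.trace_,
            column_labels=design.column_labels,
        )
        return self

    def predict(self, X):
        design = X.design if isinstance(X, InteractionDesign) else np.asarray(X, dtype=float)
        return design @ self.coef_


def fit_hierarchical_interaction(
    design: InteractionDesign,
    prior: PriorSpec | None = None,
    hyper: HyperParams | None = None,
) -> FitResult:
    """Functional entry point: fit the hierarchical model on one design."""
    hyper = hyper or HyperParams()
    est = BayesianInteractionModel(
        a=hyper.a,
        b=hyper.b,
        prior=prior,
        delta=hyper.delta,
        max_iter=hyper.max_iter,
        beta_floor=hyper.beta_floor,
    )
    est.fit(design)
    return est.result_


def fit_cpg_snp(
    bulk_meth,
    proportions,
    genotype,
    covariates=None,
    prior: PriorSpec | None = None,
    hyper: HyperParams | None = None,
    form: str = "no-intercept",
) -> FitResult:
    """Convenience wrapper: build the design for one CpG-SNP pair and fit."""
    design = build_interaction_design(
        bulk_meth, proportions, genotype, covariates=covariates, form=form
    )
    return fit_hierarchical_interaction(design, prior=prior, hyper=hyper)
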