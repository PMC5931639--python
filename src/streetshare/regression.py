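"""Regression families for city-level travel-pattern models.

Three families are implemented from first principles:

* **Beta regression** for proportion outcomes (commute mode shares,
  past-month activity prevalence).  The response is Beta-distributed in
  the mean/precision parameterisation: with mean ``mu`` and precision
  ``phi`` the density is

      f(y; mu, phi) = Gamma(phi) / (Gamma(mu*phi) * Gamma((1-mu)*phi))
                      * y**(mu*phi - 1) * (1-y)**((1-mu)*phi - 1)

  and the mean is linked to covariates through a logit link,
  ``logit(mu) = x' beta``.  The precision ``phi`` is a single constant
  estimated on the log scale.  Estimation is by maximum likelihood with
  analytic gradients.

* **Robust linear regression** by Huber M-estimation, fitted with
  iteratively reweighted least squares (IRLS) and a MAD scale
  re-estimated at each iteration.  Used for right-skewed continuous
  outcomes (days of cycling) where a few high-cycling cities would
  dominate an OLS fit.

* **Ordinary least squares** for the remaining continuous outcomes.

Standardised weighted residuals for the beta family follow the
diagnostics literature for beta regression: on the logit scale,

    r_t = (y*_t - mu*_t) / sqrt(v_t * (1 - h_tt))

with ``y* = logit(y)``, ``mu* = psi(mu*phi) - psi((1-mu)*phi)``,
``v = psi'(mu*phi) + psi'((1-mu)*phi)`` and ``h`` the leverage from the
weighted hat matrix (``psi`` the digamma, ``psi'`` the trigamma).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import optimize, special, stats

__all__ = [
    "ModelSpec",
    "FitResult",
    "beta_loglik",
    "fit_beta",
    "beta_std_residuals",
    "fit_robust_linear",
    "fit_ols",
    "fit_model",
    "predict",
    "squeeze_boundary",
]

TRANSFORMS = ("identity", "sqrt")
FAMILIES = ("beta", "robust_linear", "ols")

#: Huber tuning constant giving 95% efficiency under Gaussian errors.
HUBER_K = 1.345
#: Consistency constant for the MAD as a Gaussian scale estimate.
MAD_CONSTANT = 1.4826


@dataclass(frozen=True)
class ModelSpec:
    """A regression model: outcome, predictors with transforms, family.

    ``predictors`` is a sequence of ``(column, transform)`` pairs with
    transform one of ``"identity"`` or ``"sqrt"``.  An empty predictor
    list gives an intercept-only model.
    """

    outcome: str
    predictors: tuple = ()
    family: str = "beta"

    def __post_init__(self):
        if self.family not in FAMILIES:
            raise ValueError(f"unknown family {self.family!r}")
        preds = tuple(
            (p, "identity") if isinstance(p, str) else (p[0], p[1])
            for p in self.predictors
        )
        for col, tr in preds:
            if tr not in TRANSFORMS:
                raise ValueError(f"unknown transform {tr!r} for predictor {col!r}")
        object.__setattr__(self, "predictors", preds)

    @property
    def predictor_names(self) -> list[str]:
        return [f"sqrt({c})" if t == "sqrt" else c for c, t in self.predictors]

    def drop(self, column: str) -> "ModelSpec":
        """Spec with one predictor column removed."""
        kept = tuple(p for p in self.predictors if p[0] != column)
        if len(kept) == len(self.predictors):
            raise KeyError(column)
        return ModelSpec(self.outcome, kept, self.family)


@dataclass
class FitResult:
    spec: ModelSpec
    params: np.ndarray  # intercept first, link scale
    param_names: list[str]
    fitted: np.ndarray  # response-scale means per observation
    residuals: np.ndarray  # response-scale y - fitted
    converged: bool
    n_iter: int
    phi: float | None = None  # beta precision
    scale: float | None = None  # linear-family residual scale
    log_likelihood: float | None = None
    cov_params: np.ndarray | None = None
    nobs: int = 0

    def bse(self) -> np.ndarray:
        if self.cov_params is None:
            raise ValueError("no covariance available")
        return np.sqrt(np.diag(self.cov_params)[: len(self.params)])

    def pvalues(self) -> pd.Series:
        """Two-sided Wald p-values for the mean coefficients."""
        z = self.params / self.bse()
        p = 2.0 * stats.norm.sf(np.abs(z))
        return pd.Series(p, index=self.param_names)


def design_matrix(spec: ModelSpec, data: pd.DataFrame) -> np.ndarray:
    """Intercept-first design matrix applying the spec's transforms."""
    cols = [np.ones(len(data))]
    for col, tr in spec.predictors:
        x = np.asarray(data[col], dtype=float)
        if tr == "sqrt":
            if np.any(x < 0):
                raise ValueError(f"sqrt transform on negative values in {col!r}")
            x = np.sqrt(x)
        cols.append(x)
    return np.column_stack(cols)


def squeeze_boundary(y: np.ndarray, n: int | None = None) -> np.ndarray:
    """Shrink boundary proportions into (0, 1): y' = (y*(n-1) + 0.5) / n."""
    y = np.asarray(y, dtype=float)
    if n is None:
        n = y.size
    return (y * (n - 1) + 0.5) / n


def _check_beta_response(y: np.ndarray) -> np.ndarray:
    y = np.asarray(y, dtype=float)
    if np.any((y <= 0.0) | (y >= 1.0)):
        raise ValueError(
            "beta-family response must lie strictly inside (0, 1); "
            "apply squeeze_boundary() to boundary observations first"
        )
    return y


# ---------------------------------------------------------------------------
# Beta regression
# ---------------------------------------------------------------------------

def beta_loglik(y: np.ndarray, X: np.ndarray, beta: np.ndarray, phi: float) -> float:
    """Log-likelihood of the logit-link beta regression model."""
    y = _check_beta_response(y)
    if phi <= 0:
        raise ValueError("precision phi must be positive")
    eta = X @ np.asarray(beta, dtype=float)
    mu = special.expit(eta)
    a = mu * phi
    b = (1.0 - mu) * phi
    ll = (
        special.gammaln(phi)
        - special.gammaln(a)
        - special.gammaln(b)
        + (a - 1.0) * np.log(y)
        + (b - 1.0) * np.log1p(-y)
    )
    return float(np.sum(ll))


def _beta_negloglik_grad(theta, y, X, ystar, log_y, log_1my):
    beta = theta[:-1]
    phi = np.exp(theta[-1])
    eta = X @ beta
    # clip keeps the objective finite at extreme line-search steps
    mu = np.clip(special.expit(eta), 1e-12, 1.0 - 1e-12)
    a = mu * phi
    b = (1.0 - mu) * phi
    ll = np.sum(
        special.gammaln(phi)
        - special.gammaln(a)
        - special.gammaln(b)
        + (a - 1.0) * log_y
        + (b - 1.0) * log_1my
    )
    mustar = special.digamma(a) - special.digamma(b)
    # d ll / d beta
    dmu = mu * (1.0 - mu)
    gbeta = X.T @ (phi * (ystar - mustar) * dmu)
    # d ll / d phi, then chain through phi = exp(theta)
    gphi = np.sum(
        special.digamma(phi)
        - mu * special.digamma(a)
        - (1.0 - mu) * special.digamma(b)
        + mu * log_y
        + (1.0 - mu) * log_1my
    )
    grad = np.append(gbeta, gphi * phi)
    return -ll, -grad


def _beta_start(y, X):
    """Starting values: OLS on logit(y), method-of-moments precision."""
    ystar = special.logit(y)
    beta0, *_ = np.linalg.lstsq(X, ystar, rcond=None)
    resid = ystar - X @ beta0
    dof = max(len(y) - X.shape[1], 1)
    s2 = float(resid @ resid) / dof
    mu0 = special.expit(X @ beta0)
    with np.errstate(divide="ignore"):
        phi0 = float(np.mean(1.0 / (s2 * mu0 * (1.0 - mu0)))) - 1.0
    if not np.isfinite(phi0) or phi0 < 1.0:
        phi0 = 1.0
    return beta0, phi0


def fit_beta(
    spec: ModelSpec,
    data: pd.DataFrame,
    *,
    tol: float = 1e-8,
    maxiter: int = 500,
) -> FitResult:
    """Maximum-likelihood beta regression with logit mean link.

    The outcome column must already be on the (0, 1) proportion scale.
    Optimisation is quasi-Newton (BFGS) over ``(beta, log phi)`` with
    analytic gradients, started from OLS on the logit of the response.
    """
    y = _check_beta_response(np.asarray(data[spec.outcome], dtype=float))
    X = design_matrix(spec, data)
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise ValueError("rank-deficient design matrix")
    ystar = special.logit(y)
    log_y = np.log(y)
    log_1my = np.log1p(-y)

    beta0, phi0 = _beta_start(y, X)
    theta0 = np.append(beta0, np.log(phi0))

    res = optimize.minimize(
        _beta_negloglik_grad,
        theta0,
        args=(y, X, ystar, log_y, log_1my),
        jac=True,
        method="BFGS",
        options={"gtol": tol, "maxiter": maxiter},
    )
    theta = res.x
    beta = theta[:-1]
    phi = float(np.exp(theta[-1]))
    mu = special.expit(X @ beta)
    nll, grad = _beta_negloglik_grad(theta, y, X, ystar, log_y, log_1my)
    # gradient tolerance relative to the log-likelihood magnitude
    gtol = max(1e-5 * (1.0 + abs(nll)), 1e-6)
    converged = bool(np.linalg.norm(grad, ord=np.inf) < gtol)
    if not converged:
        import warnings

        warnings.warn(
            f"beta regression for {spec.outcome!r} did not converge "
            f"(gradient norm {np.linalg.norm(grad, ord=np.inf):.2e})",
            stacklevel=2,
        )
    cov = _beta_cov(theta, y, X, ystar, log_y, log_1my)
    ll = beta_loglik(y, X, beta, phi)
    return FitResult(
        spec=spec,
        params=beta,
        param_names=["(Intercept)"] + spec.predictor_names,
        fitted=mu,
        residuals=y - mu,
        converged=converged,
        n_iter=int(res.nit),
        phi=phi,
        log_likelihood=ll,
        cov_params=cov,
        nobs=len(y),
    )


def _beta_cov(theta, y, X, ystar, log_y, log_1my, eps: float = 1e-5):
    """Covariance of (beta, log phi) from a numerical Hessian of the
    analytic gradient; the beta block is returned on the beta scale."""
    k = len(theta)
    H = np.zeros((k, k))
    for j in range(k):
        step = eps * max(1.0, abs(theta[j]))
        tp = theta.copy()
        tp[j] += step
        tm = theta.copy()
        tm[j] -= step
        _, gp = _beta_negloglik_grad(tp, y, X, ystar, log_y, log_1my)
        _, gm = _beta_negloglik_grad(tm, y, X, ystar, log_y, log_1my)
        H[:, j] = (gp - gm) / (2 * step)
    H = 0.5 * (H + H.T)
    try:
        return np.linalg.inv(H)
    except np.linalg.LinAlgError:
        return None


def beta_std_residuals(
    fit: FitResult, y: np.ndarray | None = None, X: np.ndarray | None = None,
    data: pd.DataFrame | None = None,
) -> np.ndarray:
    """Standardised weighted residuals (variant 2) for a beta fit.

    Observations with leverage >= 1 get a NaN residual and a warning.
    """
    if fit.phi is None:
        raise ValueError("standardised residuals are defined for beta fits only")
    if data is not None:
        y = np.asarray(data[fit.spec.outcome], dtype=float)
        X = design_matrix(fit.spec, data)
    y = _check_beta_response(y)
    phi = fit.phi
    mu = special.expit(X @ fit.params)
    a = mu * phi
    b = (1.0 - mu) * phi
    ystar = special.logit(y)
    mustar = special.digamma(a) - special.digamma(b)
    v = special.polygamma(1, a) + special.polygamma(1, b)
    w = phi * v * (mu * (1.0 - mu)) ** 2
    WX = X * np.sqrt(w)[:, None]
    # hat diagonal of W^(1/2) X (X'WX)^-1 X' W^(1/2)
    Q, _ = np.linalg.qr(WX)
    h = np.sum(Q**2, axis=1)
    bad = h >= 1.0 - 1e-12
    if np.any(bad):
        import warnings

        warnings.warn(f"{int(bad.sum())} observation(s) with leverage >= 1")
    denom = np.sqrt(v * (1.0 - np.clip(h, None, 1.0 - 1e-12)))
    r = (ystar - mustar) / denom
    r[bad] = np.nan
    return r


# ---------------------------------------------------------------------------
# Robust linear regression (Huber M-estimation by IRLS)
# ---------------------------------------------------------------------------

def _mad_scale(resid: np.ndarray) -> float:
    return float(np.median(np.abs(resid))) * MAD_CONSTANT


def fit_robust_linear(
    spec: ModelSpec,
    data: pd.DataFrame,
    *,
    k: float = HUBER_K,
    tol: float = 1e-8,
    maxiter: int = 200,
) -> FitResult:
    """Huber M-regression via IRLS with MAD scale re-estimation."""
    y = np.asarray(data[spec.outcome], dtype=float)
    X = design_matrix(spec, data)
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise ValueError("rank-deficient design matrix")
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    converged = False
    it = 0
    scale = 1.0
    for it in range(1, maxiter + 1):
        resid = y - X @ beta
        scale = _mad_scale(resid)
        if scale <= 0:  # exact fit (or >= half residuals zero)
            converged = True
            break
        u = resid / scale
        w = np.where(np.abs(u) <= k, 1.0, k / np.abs(u))
        WX = X * w[:, None]
        beta_new = np.linalg.solve(X.T @ WX, WX.T @ y)
        if np.max(np.abs(beta_new - beta)) < tol:
            beta = beta_new
            converged = True
            break
        beta = beta_new
    fitted = X @ beta
    resid = y - fitted
    cov = _huber_cov(resid, X, scale, k)
    return FitResult(
        spec=spec,
        params=beta,
        param_names=["(Intercept)"] + spec.predictor_names,
        fitted=fitted,
        residuals=resid,
        converged=converged,
        n_iter=it,
        scale=scale,
        cov_params=cov,
        nobs=len(y),
    )


def _huber_cov(resid, X, scale, k):
    """Huber's asymptotic covariance for the M-estimator."""
    n, p = X.shape
    if scale <= 0:
        return np.zeros((p, p))
    u = resid / scale
    psi = np.clip(u, -k, k)
    psi_prime = (np.abs(u) <= k).astype(float)
    m1 = np.mean(psi_prime)
    if m1 <= 0:
        return None
    kappa = 1.0 + p / n * np.var(psi_prime) / m1**2  # small-sample correction
    s2 = scale**2 * np.sum(psi**2) / (n - p) / m1**2 * kappa
    return s2 * np.linalg.inv(X.T @ X)


# ---------------------------------------------------------------------------
# Ordinary least squares
# ---------------------------------------------------------------------------

def fit_ols(spec: ModelSpec, data: pd.DataFrame) -> FitResult:
    y = np.asarray(data[spec.outcome], dtype=float)
    X = design_matrix(spec, data)
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise ValueError("rank-deficient design matrix")
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    fitted = X @ beta
    resid = y - fitted
    dof = max(len(y) - X.shape[1], 1)
    s2 = float(resid @ resid) / dof
    cov = s2 * np.linalg.inv(X.T @ X)
    return FitResult(
        spec=spec,
        params=beta,
        param_names=["(Intercept)"] + spec.predictor_names,
        fitted=fitted,
        residuals=resid,
        converged=True,
        n_iter=1,
        scale=float(np.sqrt(s2)),
        cov_params=cov,
        nobs=len(y),
    )


_FITTERS = {"beta": fit_beta, "robust_linear": fit_robust_linear, "ols": fit_ols}


def fit_model(spec: ModelSpec, data: pd.DataFrame) -> FitResult:
    """Dispatch to the family's fitter."""
    return _FITTERS[spec.family](spec, data)


def predict(fit: FitResult, data: pd.DataFrame) -> np.ndarray:
    """Response-scale predictions for new rows (logistic inverse link for
    the beta family, identity for the linear families)."""
    X = design_matrix(fit.spec, data)
    eta = X @ fit.params
    if fit.spec.family == "beta":
        return special.expit(eta)
    return eta
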