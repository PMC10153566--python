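"""Censored (Tobit) regression by maximum likelihood.

The model is a latent linear regression y* = X b + e, e ~ N(0, sigma^2),
observed as y = max(L, min(U, y*)) for censoring limits L (lower) and U
(upper), either of which may be absent.  Interior observations contribute
normal log-densities, censored observations the corresponding tail
log-probabilities:

    ll = sum_{L<y<U} log phi((y - Xb)/sigma) - log sigma
       + sum_{y=L} log Phi((L - Xb)/sigma)
       + sum_{y=U} log Phi((Xb - U)/sigma)

With both limits absent the likelihood is exactly Gaussian regression, so
the ML coefficients coincide with OLS and sigma^2 with the n-denominator
residual variance; this serves as a closed-form cross-check.

Fitting maximises the log-likelihood with BFGS on (b, log sigma) using the
analytic gradient, started from OLS.  Standard errors come from the inverse
observed information (numerical Hessian in the (b, sigma) parametrisation),
T-ratios and p-values use the normal reference, and the LR chi-square
compares against the intercept-only model, matching the conventions of the
usual econometric software output for this model.

In the two-stage efficiency analysis the dependent variable is the combined
super-efficiency score, which is bounded below but exceeds 1 for frontier
units; the default limits are therefore lower=0, upper=absent, and both are
configurable.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats
from statsmodels.tools import numdiff

from .errors import SolverError

__all__ = ["TobitSpec", "TobitFit", "tobit_loglik", "fit_tobit"]

_LOG_SQRT_2PI = 0.5 * np.log(2.0 * np.pi)


@dataclass(frozen=True)
class TobitSpec:
    """Censoring limits and fitting options.

    ``lower_limit``/``upper_limit`` of ``None`` mean uncensored on that side
    (the model then degrades gracefully toward plain Gaussian ML).
    ``standardize`` centres/scales non-constant regressors internally and
    maps the estimates back, which only affects numerical conditioning.
    """

    lower_limit: float | None = 0.0
    upper_limit: float | None = None
    standardize: bool = False
    ci_level: float = 0.95

    def __post_init__(self) -> None:
        if self.lower_limit is not None and self.upper_limit is not None:
            if not self.lower_limit < self.upper_limit:
                raise ValueError("lower_limit must be strictly below upper_limit")
        if not 0.0 < self.ci_level < 1.0:
            raise ValueError("ci_level must be in (0, 1)")


def _censor_masks(y: np.ndarray, spec: TobitSpec):
    lo = np.zeros(len(y), dtype=bool) if spec.lower_limit is None else y <= spec.lower_limit
    hi = np.zeros(len(y), dtype=bool) if spec.upper_limit is None else y >= spec.upper_limit
    mid = ~(lo | hi)
    return lo, mid, hi


def tobit_loglik(
    beta: np.ndarray, sigma: float, X: np.ndarray, y: np.ndarray, spec: TobitSpec
) -> float:
    """Censored-normal log-likelihood at (beta, sigma)."""
    beta = np.asarray(beta, dtype=float)
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    if sigma <= 0:
        raise ValueError("sigma must be positive")
    if not (np.all(np.isfinite(beta)) and np.all(np.isfinite(X)) and np.all(np.isfinite(y))):
        raise ValueError("non-finite inputs to tobit_loglik")
    mu = X @ beta
    lo, mid, hi = _censor_masks(y, spec)
    ll = 0.0
    if mid.any():
        z = (y[mid] - mu[mid]) / sigma
        ll += float(np.sum(-0.5 * z * z - _LOG_SQRT_2PI - np.log(sigma)))
    if lo.any():
        ll += float(np.sum(stats.norm.logcdf((spec.lower_limit - mu[lo]) / sigma)))
    if hi.any():
        ll += float(np.sum(stats.norm.logcdf((mu[hi] - spec.upper_limit) / sigma)))
    return ll


def _loglik_and_grad(theta: np.ndarray, X: np.ndarray, y: np.ndarray, spec: TobitSpec):
    """(ll, grad) in the (beta, log sigma) parametrisation."""
    beta, logsig = theta[:-1], theta[-1]
    sigma = np.exp(logsig)
    mu = X @ beta
    lo, mid, hi = _censor_masks(y, spec)

    ll = 0.0
    dmu = np.zeros(len(y))  # d ll / d mu_i
    dlogsig = 0.0

    if mid.any():
        z = (y[mid] - mu[mid]) / sigma
        ll += np.sum(-0.5 * z * z - _LOG_SQRT_2PI) - mid.sum() * np.log(sigma)
        dmu[mid] = z / sigma
        dlogsig += float(np.sum(z * z - 1.0))
    if lo.any():
        a = (spec.lower_limit - mu[lo]) / sigma
        ll += float(np.sum(stats.norm.logcdf(a)))
        ratio = np.exp(stats.norm.logpdf(a) - stats.norm.logcdf(a))  # inverse Mills
        dmu[lo] = -ratio / sigma
        dlogsig += float(np.sum(-ratio * a))
    if hi.any():
        a = (mu[hi] - spec.upper_limit) / sigma
        ll += float(np.sum(stats.norm.logcdf(a)))
        ratio = np.exp(stats.norm.logpdf(a) - stats.norm.logcdf(a))
        dmu[hi] = ratio / sigma
        dlogsig += float(np.sum(-ratio * a))

    grad = np.r_[X.T @ dmu, dlogsig]
    return float(ll), grad


@dataclass(frozen=True)
class TobitFit:
    """ML estimates and inference table for one censored regression."""

    beta: np.ndarray
    sigma: float
    se: np.ndarray  # SEs for beta then sigma, length p+1... (len(beta)+1)
    t_ratios: np.ndarray
    p_values: np.ndarray
    ci: np.ndarray  # (len(beta)+1, 2) rows: each beta, then sigma
    loglik: float
    lr_chi2: float
    lr_p: float
    n_obs: int
    n_censored_low: int
    n_censored_high: int
    converged: bool
    names: tuple[str, ...] = field(default=())

    def summary_frame(self) -> pd.DataFrame:
        """Coefficient table: coefficient, SE, T-ratio, p, CI bounds (sigma last)."""
        labels = list(self.names) if self.names else [f"x{j}" for j in range(len(self.beta))]
        labels.append("Sigma")
        est = np.r_[self.beta, self.sigma]
        tr = np.r_[self.t_ratios, np.nan]
        pv = np.r_[self.p_values, np.nan]
        return pd.DataFrame(
            {
                "coefficient": est,
                "SE": self.se,
                "T-ratio": tr,
                "p": pv,
                "ci_low": self.ci[:, 0],
                "ci_high": self.ci[:, 1],
            },
            index=labels,
        )


def _maximize(X: np.ndarray, y: np.ndarray, spec: TobitSpec, theta0: np.ndarray):
    def negll(theta):
        ll, g = _loglik_and_grad(theta, X, y, spec)
        return -ll, -g

    res = optimize.minimize(
        negll, theta0, jac=True, method="BFGS", options={"gtol": 1e-8, "maxiter": 500}
    )
    if not np.all(np.isfinite(res.x)):
        raise SolverError("tobit optimisation diverged to non-finite parameters")
    # BFGS may stop on "precision loss" with the gradient already tiny
    res.success = bool(res.success or np.linalg.norm(res.jac) < 1e-6)
    return res


def fit_tobit(
    X: np.ndarray,
    y: np.ndarray,
    spec: TobitSpec = TobitSpec(),
    names: tuple[str, ...] | None = None,
) -> TobitFit:
    """Fit the Tobit model by maximum likelihood.

    ``X`` is the full design matrix (include an intercept column yourself,
    conventionally first); ``names`` labels its columns in the summary.
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    y = np.asarray(y, dtype=float).ravel()
    n, p1 = X.shape
    if n != len(y):
        raise ValueError("X and y length mismatch")
    if n <= p1 + 2:
        raise ValueError(f"need n > p + 2 observations (n={n}, columns={p1})")
    rank = np.linalg.matrix_rank(X)
    if rank < p1:
        sing = [j for j in range(p1) if np.linalg.matrix_rank(np.delete(X, j, axis=1)) == rank]
        labels = [names[j] if names else f"column {j}" for j in sing]
        raise ValueError(f"design matrix is rank deficient; collinear columns include {labels}")

    const_cols = np.all(X == X[0, :], axis=0)
    if spec.standardize:
        mean = np.where(const_cols, 0.0, X.mean(axis=0))
        scale = np.where(const_cols, 1.0, X.std(axis=0, ddof=0))
        scale = np.where(scale == 0, 1.0, scale)
        Xw = (X - mean) / scale
    else:
        mean = np.zeros(p1)
        scale = np.ones(p1)
        Xw = X

    # OLS start
    beta0, *_ = np.linalg.lstsq(Xw, y, rcond=None)
    resid = y - Xw @ beta0
    sig0 = float(np.sqrt(np.mean(resid**2)))
    sig0 = max(sig0, 1e-6)
    theta0 = np.r_[beta0, np.log(sig0)]

    res = _maximize(Xw, y, spec, theta0)
    beta_w = res.x[:-1]
    sigma = float(np.exp(res.x[-1]))
    ll = -float(res.fun)

    # de-standardize: y = Xw bw = ((X - mean)/scale) bw
    beta = beta_w / scale
    if spec.standardize and const_cols.any():
        j0 = int(np.argmax(const_cols))
        beta[j0] -= float(np.sum(mean * beta_w / scale)) / X[0, j0]

    # observed information in the (beta, sigma) parametrisation, original scale
    def ll_bs(params):
        return tobit_loglik(params[:-1], params[-1], X, y, spec)

    theta_bs = np.r_[beta, sigma]
    hess = numdiff.approx_hess(theta_bs, ll_bs)
    try:
        cov = np.linalg.inv(-hess)
    except np.linalg.LinAlgError:
        cov = np.linalg.pinv(-hess)
    var = np.diag(cov).copy()
    var[var < 0] = np.nan
    se = np.sqrt(var)

    zcrit = stats.norm.ppf(0.5 + spec.ci_level / 2.0)
    t_ratios = beta / se[:-1]
    p_values = 2.0 * stats.norm.sf(np.abs(t_ratios))
    ci = np.c_[theta_bs - zcrit * se, theta_bs + zcrit * se]

    # LR test against the intercept-only model
    ones = np.ones((n, 1))
    beta_n0 = np.array([np.mean(y)])
    sig_n0 = max(float(np.std(y, ddof=0)), 1e-6)
    res0 = _maximize(ones, y, spec, np.r_[beta_n0, np.log(sig_n0)])
    ll0 = -float(res0.fun)
    lr = max(2.0 * (ll - ll0), 0.0)
    df = max(p1 - 1, 1)
    lr_p = float(stats.chi2.sf(lr, df))

    lo, _, hi = _censor_masks(y, spec)
    return TobitFit(
        beta=beta,
        sigma=sigma,
        se=se,
        t_ratios=t_ratios,
        p_values=p_values,
        ci=ci,
        loglik=ll,
        lr_chi2=lr,
        lr_p=lr_p,
        n_obs=n,
        n_censored_low=int(lo.sum()),
        n_censored_high=int(hi.sum()),
        converged=bool(res.success),
        names=tuple(names) if names else tuple(f"x{j}" for j in range(p1)),
    )
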