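"""Beta-regression MLE for FO error rates and a logistic fit of pool
detection against within-individual frequency.

The beta regression uses a logit link for the mean and an intercept-only
log-linked precision phi (shapes mu*phi and (1-mu)*phi), maximized by
quasi-Newton with analytic gradients.  Responses on the [0, 1] boundary
are compressed into (0, 1) with y' = (y (N - 1) + 0.5) / N before
fitting (Smithson & Verkuilen).  The pseudo R-squared is the squared
Pearson correlation between logit(y) and the fitted linear predictor.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, special

__all__ = [
    "BetaRegFit",
    "LogisticFit",
    "beta_design",
    "fit_betareg",
    "pseudo_r2",
    "fit_pool_detection",
    "compress_unit_interval",
]

DESIGN_COLUMNS = [
    "intercept",
    "n",
    "fo_tot",
    "fo_pel",
    "n:fo_tot",
    "n:fo_pel",
    "fo_tot:fo_pel",
    "n:fo_tot:fo_pel",
]


@dataclass
class BetaRegFit:
    """Fitted beta regression: mean-submodel coefficients (logit link),
    precision phi (log link, intercept-only), and fit diagnostics."""

    coef: pd.Series
    phi: float
    loglik: float
    converged: bool
    iterations: int
    se: pd.Series | None = None
    pseudo_r2: float | None = None

    def predict(self, X: np.ndarray) -> np.ndarray:
        eta = np.asarray(X, dtype=float) @ self.coef.to_numpy()
        return _sigmoid(eta)


@dataclass
class LogisticFit:
    """Fixed-effect logistic regression fit."""

    coef: pd.Series
    se: pd.Series
    z: pd.Series
    converged: bool
    loglik: float = field(default=np.nan)


def _sigmoid(x):
    return 1.0 / (1.0 + np.exp(-np.clip(x, -700, 700)))


def compress_unit_interval(y: np.ndarray, n: int | None = None) -> np.ndarray:
    """Shrink [0, 1] responses into (0, 1): y' = (y (N-1) + 0.5) / N."""
    y = np.asarray(y, dtype=float)
    if ((y < 0) | (y > 1)).any():
        raise ValueError("responses must lie in [0, 1] before compression")
    N = len(y) if n is None else n
    return (y * (N - 1) + 0.5) / N


def beta_design(errors, fo: pd.DataFrame) -> tuple[pd.DataFrame, np.ndarray]:
    """Design matrix and compressed response for the error-rate model.

    One row per (taxon, n) from an :class:`~dietrep.fo.ErrorDistribution`
    (relative kind); covariates are n, fo_tot, fo_pel and all their
    interactions.  The response is the mean error, compressed into (0,1).
    """
    if errors.error_kind != "relative":
        raise ValueError("beta regression expects relative error rates")
    tab = errors.table.merge(
        fo[["fo_tot", "fo_pel"]], left_on="taxon", right_index=True, how="left"
    )
    if tab[["fo_tot", "fo_pel"]].isna().any().any():
        raise ValueError("missing FO covariates for some taxa")
    y = compress_unit_interval(tab["mean_error"].to_numpy())
    X = pd.DataFrame(
        {
            "intercept": 1.0,
            "n": tab["n"].astype(float),
            "fo_tot": tab["fo_tot"],
            "fo_pel": tab["fo_pel"],
        }
    )
    X["n:fo_tot"] = X["n"] * X["fo_tot"]
    X["n:fo_pel"] = X["n"] * X["fo_pel"]
    X["fo_tot:fo_pel"] = X["fo_tot"] * X["fo_pel"]
    X["n:fo_tot:fo_pel"] = X["n"] * X["fo_tot"] * X["fo_pel"]
    X.index = pd.MultiIndex.from_frame(tab[["taxon", "n"]])
    return X[DESIGN_COLUMNS], y


def _beta_negll_grad(theta, X, y):
    k = X.shape[1]
    beta, log_phi = theta[:k], theta[k]
    phi = np.exp(log_phi)
    eta = X @ beta
    mu = _sigmoid(eta)
    a = mu * phi
    b = (1 - mu) * phi
    ll = (
        special.gammaln(phi)
        - special.gammaln(a)
        - special.gammaln(b)
        + (a - 1) * np.log(y)
        + (b - 1) * np.log1p(-y)
    ).sum()
    ystar = np.log(y) - np.log1p(-y)
    mustar = special.digamma(a) - special.digamma(b)
    # d ll / d beta  (mu'(eta) = mu (1 - mu))
    gbeta = X.T @ (phi * (ystar - mustar) * mu * (1 - mu))
    gphi = (
        special.digamma(phi)
        - mu * special.digamma(a)
        - (1 - mu) * special.digamma(b)
        + mu * np.log(y)
        + (1 - mu) * np.log1p(-y)
    ).sum() * phi  # chain rule through log_phi
    return -ll, -np.concatenate([gbeta, [gphi]])


def fit_betareg(X, y, max_iter: int = 200, tol: float = 1e-10) -> BetaRegFit:
    """Maximum-likelihood beta regression.

    Starts from an OLS fit of logit(y) and a method-of-moments phi, then
    maximizes the beta log-likelihood by L-BFGS-B with analytic
    gradients.  Raises on rank-deficient X; non-convergence returns the
    partial fit with ``converged=False``.
    """
    names = (
        list(X.columns)
        if isinstance(X, pd.DataFrame)
        else [f"x{i}" for i in range(np.asarray(X).shape[1])]
    )
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    if ((y <= 0) | (y >= 1)).any():
        raise ValueError("y must lie strictly in (0, 1); compress first")
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise ValueError("design matrix is rank deficient")

    logit_y = np.log(y) - np.log1p(-y)
    beta0, *_ = np.linalg.lstsq(X, logit_y, rcond=None)
    mu0 = _sigmoid(X @ beta0)
    resid = y - mu0
    var = max(resid.var(), 1e-6)
    phi0 = max(np.mean(mu0 * (1 - mu0)) / var - 1, 1.0)

    res = optimize.minimize(
        _beta_negll_grad,
        np.concatenate([beta0, [np.log(phi0)]]),
        args=(X, y),
        jac=True,
        method="L-BFGS-B",
        bounds=[(None, None)] * X.shape[1] + [(-10.0, 25.0)],  # log phi kept finite
        options={"maxiter": max_iter, "ftol": tol, "gtol": 1e-8},
    )
    k = X.shape[1]
    beta_hat = res.x[:k]
    phi_hat = float(np.exp(res.x[k]))
    se = None
    try:
        hess = _numeric_hessian(lambda th: _beta_negll_grad(th, X, y)[0], res.x)
        cov = np.linalg.inv(hess)
        d = np.diag(cov)
        if (d[:k] > 0).all():
            se = pd.Series(np.sqrt(d[:k]), index=names)
    except np.linalg.LinAlgError:
        pass
    fit = BetaRegFit(
        coef=pd.Series(beta_hat, index=names),
        phi=phi_hat,
        loglik=-float(res.fun),
        converged=bool(res.success),
        iterations=int(res.nit),
        se=se,
    )
    fit.pseudo_r2 = pseudo_r2(fit, y, X)
    return fit


def _numeric_hessian(f, x, eps: float = 1e-5) -> np.ndarray:
    n = len(x)
    h = np.empty((n, n))
    for i in range(n):
        for j in range(i, n):
            pp = x.copy(); pp[i] += eps; pp[j] += eps
            pm = x.copy(); pm[i] += eps; pm[j] -= eps
            mp = x.copy(); mp[i] -= eps; mp[j] += eps
            mm = x.copy(); mm[i] -= eps; mm[j] -= eps
            h[i, j] = h[j, i] = (f(pp) - f(pm) - f(mp) + f(mm)) / (4 * eps * eps)
    return h


def pseudo_r2(fit: BetaRegFit, y, X=None) -> float:
    """Squared Pearson correlation between logit(y) and the fitted
    linear predictor; missing (NaN) when either side has zero variance."""
    y = np.asarray(y, dtype=float)
    if X is None:
        raise ValueError("X required to evaluate the linear predictor")
    eta = np.asarray(X, dtype=float) @ fit.coef.to_numpy()
    logit_y = np.log(y) - np.log1p(-y)
    if np.std(eta) == 0 or np.std(logit_y) == 0:
        return np.nan
    return float(np.corrcoef(logit_y, eta)[0, 1] ** 2)


def fit_pool_detection(detections, fopel) -> LogisticFit:
    """Logistic regression of pool detection on within-individual
    frequency: detected ~ fo_pel over (individual, taxon) pairs with the
    taxon present in that individual's pellets.

    Fixed-effect IRLS fit (statsmodels GLM); complete separation (or a
    constant response) raises with a diagnostic.
    """
    import statsmodels.api as sm
    from statsmodels.tools.sm_exceptions import PerfectSeparationError

    y = np.asarray(detections, dtype=float)
    x = np.asarray(fopel, dtype=float)
    if set(np.unique(y)) - {0.0, 1.0}:
        raise ValueError("detections must be binary")
    if len(np.unique(y)) < 2:
        raise ValueError("complete separation: response is constant")
    X = sm.add_constant(pd.DataFrame({"fo_pel": x}))
    model = sm.GLM(y, X, family=sm.families.Binomial())
    try:
        with np.errstate(all="ignore"):
            res = model.fit(maxiter=100)
    except PerfectSeparationError as exc:
        raise ValueError(f"complete separation in logistic fit: {exc}") from exc
    mu = res.predict(X)
    if np.all((mu > 0.999) == (y > 0.5)) and np.all((mu < 0.001) == (y < 0.5)):
        raise ValueError("complete separation: fitted probabilities are 0/1")
    params = res.params
    names = ["intercept", "fo_pel"]
    return LogisticFit(
        coef=pd.Series(params.to_numpy(), index=names),
        se=pd.Series(res.bse.to_numpy(), index=names),
        z=pd.Series((params / res.bse).to_numpy(), index=names),
        converged=bool(res.converged),
        loglik=float(res.llf),
    )
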