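"""Robust regression estimators.

``HuberRegression`` is a Huber M-estimator fitted by iteratively
reweighted least squares: coefficients solve

    sum_i psi_c((y_i - x_i' beta) / sigma) x_i = 0,

with psi_c the Huber influence function (identity inside [-c, c],
clamped outside) and sigma the median absolute residual rescaled by
1/0.6745, re-estimated every iteration.  With the default c = 1.345 the
estimator has ~95% Gaussian efficiency while bounding the influence of
outlying observations.  Standard errors use the Huber "H1" asymptotic
covariance with the small-sample correction factor, and p-values /
confidence intervals use a t reference with n - p degrees of freedom.

``DetectionLogistic`` fits the binary detectable-vs-not models by
maximum-likelihood logistic regression (IRLS via statsmodels GLM), with
complete separation flagged rather than raised.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import statsmodels.api as sm
from scipy import stats
from sklearn.base import BaseEstimator, RegressorMixin

__all__ = ["HuberConfig", "HuberRegression", "DetectionLogistic"]

#: MAD consistency constant for the Gaussian: Phi^{-1}(3/4).
_MAD_SCALE = 0.6744897501960817


@dataclass(frozen=True)
class HuberConfig:
    """Tuning for the Huber M-estimator."""

    c: float = 1.345
    max_iter: int = 300
    tol: float = 1e-8
    use_t: bool = True  # t_{n-p} reference for p-values / CIs

    def __post_init__(self):
        if self.c <= 0:
            raise ValueError("tuning constant c must be > 0")
        if self.tol <= 0:
            raise ValueError("tolerance must be > 0")


def _check_design(X: np.ndarray, y: np.ndarray, names=None):
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    if X.ndim != 2:
        raise ValueError("X must be 2-dimensional")
    n, p = X.shape
    if y.size != n:
        raise ValueError("X and y have incompatible shapes")
    if n <= p:
        raise ValueError(f"need n > p (got n={n}, p={p})")
    if not (np.isfinite(X).all() and np.isfinite(y).all()):
        raise ValueError("missing or non-finite values in the model frame; "
                         "drop incomplete rows upstream")
    rank = np.linalg.matrix_rank(X)
    if rank < p:
        names = list(names) if names is not None else [f"x{j}" for j in range(p)]
        # point at columns whose removal restores full rank
        collinear = []
        for j in range(p):
            keep = [k for k in range(p) if k != j]
            if np.linalg.matrix_rank(X[:, keep]) == rank:
                collinear.append(names[j])
        raise ValueError(f"design matrix is rank deficient; collinear columns: {collinear}")
    return X, y


class HuberRegression(RegressorMixin, BaseEstimator):
    """Huber M-estimation linear regression (IRLS, MAD scale).

    Parameters
    ----------
    c : float
        Huber tuning constant (default 1.345).
    fit_intercept : bool
        Prepend a constant column (default True).
    max_iter, tol : IRLS stopping rule (max relative coefficient change).
    use_t : bool
        Use a t_{n-p} reference for inference (else normal).

    Attributes (after ``fit``)
    --------------------------
    coef_, intercept_ : point estimates.
    params_ : full coefficient vector (intercept first when fitted).
    bse_ : standard errors;  pvalues_ : two-sided p-values.
    scale_ : final MAD residual scale.
    converged_ : whether IRLS met the tolerance.
    """

    def __init__(self, c: float = 1.345, fit_intercept: bool = True,
                 max_iter: int = 300, tol: float = 1e-8, use_t: bool = True):
        self.c = c
        self.fit_intercept = fit_intercept
        self.max_iter = max_iter
        self.tol = tol
        self.use_t = use_t

    # -- internals --------------------------------------------------------
    def _psi(self, u):
        return np.clip(u, -self.c, self.c)

    def _psi_deriv(self, u):
        return (np.abs(u) <= self.c).astype(float)

    def fit(self, X, y, feature_names=None):
        cfg = HuberConfig(c=self.c, max_iter=self.max_iter, tol=self.tol,
                          use_t=self.use_t)
        X = np.asarray(X, dtype=float)
        if X.ndim == 1:
            X = X[:, None]
        names = list(feature_names) if feature_names is not None else [
            f"x{j}" for j in range(X.shape[1])
        ]
        if self.fit_intercept:
            X = np.column_stack([np.ones(X.shape[0]), X])
            names = ["const"] + names
        X, y = _check_design(X, y, names)
        n, p = X.shape

        beta, *_ = np.linalg.lstsq(X, y, rcond=None)
        converged = False
        scale = np.nan
        y_scale = max(1.0, float(np.abs(y).max()))
        for _ in range(cfg.max_iter):
            resid = y - X @ beta
            scale = np.median(np.abs(resid)) / _MAD_SCALE
            if np.abs(resid).max() <= 1e-10 * y_scale:
                # perfect fit: the LS solution is the M-estimate
                converged = True
                scale = 0.0
                break
            if scale <= 1e-12 * y_scale or not np.isfinite(scale):
                raise ValueError(
                    "degenerate fit: residual MAD is zero (constant or "
                    "near-constant outcome)"
                )
            u = resid / scale
            with np.errstate(divide="ignore"):
                w = np.where(np.abs(u) <= cfg.c, 1.0, cfg.c / np.abs(u))
            sw = np.sqrt(w)
            beta_new, *_ = np.linalg.lstsq(X * sw[:, None], y * sw, rcond=None)
            step = np.max(np.abs(beta_new - beta)) / max(1.0, np.max(np.abs(beta)))
            beta = beta_new
            if step < cfg.tol:
                converged = True
                break
        if not converged:
            warnings.warn("Huber IRLS did not converge; result flagged")

        # H1-type asymptotic covariance (Huber 1981 small-sample correction)
        if scale > 0:
            resid = y - X @ beta
            u = resid / scale
            psi = self._psi(u)
            dpsi = self._psi_deriv(u)
            m1 = dpsi.mean()
            k = 1.0 + (p / n) * dpsi.var() / m1**2
            s2 = (psi**2).sum() * scale**2 / (n - p)
            cov = k**2 * (s2 / m1**2) * np.linalg.inv(X.T @ X)
            bse = np.sqrt(np.diag(cov))
        else:
            cov = np.zeros((p, p))
            bse = np.zeros(p)

        self.names_ = names
        self.params_ = beta
        self.cov_params_ = cov
        self.bse_ = bse
        self.scale_ = float(scale)
        self.converged_ = bool(converged)
        self.df_resid_ = n - p
        self.n_obs_ = n
        if self.fit_intercept:
            self.intercept_ = float(beta[0])
            self.coef_ = beta[1:]
        else:
            self.intercept_ = 0.0
            self.coef_ = beta
        with np.errstate(divide="ignore", invalid="ignore"):
            tvals = np.where(bse > 0, beta / bse, np.inf * np.sign(beta))
        if cfg.use_t:
            self.pvalues_ = 2 * stats.t.sf(np.abs(tvals), self.df_resid_)
        else:
            self.pvalues_ = 2 * stats.norm.sf(np.abs(tvals))
        self.tvalues_ = tvals
        return self

    def predict(self, X):
        X = np.asarray(X, dtype=float)
        if X.ndim == 1:
            X = X[:, None]
        return self.intercept_ + X @ self.coef_

    def conf_int(self, alpha: float = 0.05) -> np.ndarray:
        """(p, 2) array of confidence bounds for all coefficients."""
        if self.use_t:
            q = stats.t.ppf(1 - alpha / 2, self.df_resid_)
        else:
            q = stats.norm.ppf(1 - alpha / 2)
        return np.column_stack([self.params_ - q * self.bse_,
                                self.params_ + q * self.bse_])


class DetectionLogistic(BaseEstimator):
    """ML logistic regression for binary detectable-vs-not outcomes.

    Wald standard errors and normal-reference p-values on the log-odds
    scale.  Complete (quasi-)separation and non-convergence set
    ``converged_ = False`` with a diagnostic in ``note_`` instead of
    raising, so batch per-miRNA runs can skip and log.
    """

    #: |fitted log-odds| beyond which we call the fit separated
    _SEPARATION_LOGIT = 20.0

    def __init__(self, fit_intercept: bool = True):
        self.fit_intercept = fit_intercept

    def fit(self, X, y, feature_names=None):
        X = np.asarray(X, dtype=float)
        if X.ndim == 1:
            X = X[:, None]
        y = np.asarray(y, dtype=float).ravel()
        if not set(np.unique(y)) <= {0.0, 1.0}:
            raise ValueError("outcome must be binary 0/1")
        names = list(feature_names) if feature_names is not None else [
            f"x{j}" for j in range(X.shape[1])
        ]
        if self.fit_intercept:
            X = np.column_stack([np.ones(X.shape[0]), X])
            names = ["const"] + names
        if y.min() == y.max():
            raise ValueError("single-class outcome: both classes must be present")
        _check_design(X, y, names)
        self.names_ = names
        self.note_ = ""
        self.converged_ = True
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            try:
                res = sm.GLM(y, X, family=sm.families.Binomial()).fit(maxiter=100)
            except Exception as exc:  # singular weights under separation
                self.converged_ = False
                self.note_ = f"logistic fit failed: {exc}"
                p = X.shape[1]
                self.params_ = np.full(p, np.nan)
                self.bse_ = np.full(p, np.nan)
                self.pvalues_ = np.full(p, np.nan)
                return self
        eta = X @ res.params
        if not res.converged or np.abs(eta).max() > self._SEPARATION_LOGIT:
            self.converged_ = False
            self.note_ = "possible complete separation or non-convergence"
        self.params_ = np.asarray(res.params)
        self.bse_ = np.asarray(res.bse)
        self.pvalues_ = np.asarray(res.pvalues)
        self.cov_params_ = np.asarray(res.cov_params())
        self.df_resid_ = res.df_resid
        self.n_obs_ = int(res.nobs)
        if self.fit_intercept:
            self.intercept_ = float(self.params_[0])
            self.coef_ = self.params_[1:]
        else:
            self.intercept_ = 0.0
            self.coef_ = self.params_
        return self

    def predict_proba(self, X):
        X = np.asarray(X, dtype=float)
        if X.ndim == 1:
            X = X[:, None]
        eta = self.intercept_ + X @ self.coef_
        p1 = 1.0 / (1.0 + np.exp(-eta))
        return np.column_stack([1 - p1, p1])

    def conf_int(self, alpha: float = 0.05) -> np.ndarray:
        q = stats.norm.ppf(1 - alpha / 2)
        return np.column_stack([self.params_ - q * self.bse_,
                                self.params_ + q * self.bse_])
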