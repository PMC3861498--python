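"""Intercept-corrected logistic regression for case-base data.

Fitting an ordinary logistic regression of disease status on the covariates
*within the recruited case-base sample* yields consistent log odds ratios,
but an intercept alpha* that is shifted away from the population intercept
alpha = log q: case sampling over-represents the diseased by the factor
1/rho, where rho is the probability that a recruited diseased subject is in
the base sample. Because the likelihood of the recruited data factorizes
into three pieces — a binomial for gamma, a binomial for rho and the
logistic regression for (alpha*, beta) — the three blocks are orthogonal,
and the correction is a one-liner:

    alpha_hat = alpha*_hat + log rho_hat,      rho_hat = n1 / n_D,

with n1 the number of diseased subjects recruited in the base sample and
n_D the number of distinct diseased recruits. Absolute risks follow from
the corrected model, and their uncertainty adds the (independent) binomial
variance of log rho_hat to the usual Wald variance:

    var(logit p_hat(x))  = z V z' + var(log rho_hat),  z = (1, x)
    var(log RR(x1, x0))  = h V h' + c^2 var(log rho_hat),
        h = [(1-p1) - (1-p0), (1-p1) x1 - (1-p0) x0],  c = (1-p1) - (1-p0)

where V is the covariance of (alpha*, beta) from the logistic fit and
var(log rho_hat) = (1 - rho_hat) / (n_D rho_hat) by the delta method.

The module exposes a scikit-learn style estimator,
:class:`CaseBaseRegression`, plus functional wrappers operating on
case-base dataset frames (`fit_casebase`, `estimate_risk`, ...).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy.special import expit
from scipy.stats import norm
from sklearn.base import BaseEstimator
from sklearn.utils.validation import check_array, check_is_fitted, check_X_y

from .design import TermEncoder, build_matrix
from .errors import (NotEstimableError, RankDeficientError, SeparationError,
                     ValidationError)
from .sampling import SamplingCounts, tabulate_counts, validate_dataset

__all__ = [
    "LogisticFit",
    "RhoGammaEstimate",
    "CaseBaseFit",
    "EffectEstimate",
    "CaseBaseRegression",
    "fit_sample_logistic",
    "estimate_rho_gamma",
    "fit_casebase",
    "estimate_risk",
    "estimate_rr",
    "estimate_or",
]

#: coefficients beyond this magnitude are treated as diverging (separation)
_SEPARATION_BOUND = 30.0


@dataclass
class LogisticFit:
    """Sample-model logistic fit: intercept alpha*, slopes and covariance."""

    alpha_star: float
    beta: np.ndarray
    covariance: np.ndarray        # (1+p) x (1+p), over (alpha*, beta)
    columns: list[str]
    converged: bool
    n_iter: int

    @property
    def params(self) -> np.ndarray:
        return np.concatenate([[self.alpha_star], self.beta])


@dataclass
class RhoGammaEstimate:
    """Binomial estimates of the sampling parameters rho and gamma.

    rho_hat = n1/n_D with var(rho_hat) = rho(1-rho)/n_D and, by the delta
    method, var(log rho_hat) = (1-rho)/(n_D rho). gamma_hat = n11/n1 is a
    nuisance parameter and may be unavailable (NaN) without consequence.
    """

    n_D: int
    n1: int
    n11: int
    rho_hat: float = field(init=False)
    var_rho: float = field(init=False)
    var_log_rho: float = field(init=False)
    gamma_hat: float = field(init=False)
    var_gamma: float = field(init=False)

    def __post_init__(self) -> None:
        if self.n_D < 1:
            raise ValidationError("n_D must be >= 1 to estimate rho")
        if not 0 <= self.n11 <= self.n1 <= self.n_D:
            raise ValidationError("counts must satisfy 0 <= n11 <= n1 <= n_D")
        if self.n1 > 0:
            self.rho_hat = self.n1 / self.n_D
            self.var_rho = self.rho_hat * (1.0 - self.rho_hat) / self.n_D
            self.var_log_rho = (1.0 - self.rho_hat) / (self.n_D * self.rho_hat)
            self.gamma_hat = self.n11 / self.n1 if self.n11 > 0 else np.nan
            self.var_gamma = (self.gamma_hat * (1.0 - self.gamma_hat) / self.n1
                              if self.n11 > 0 else np.nan)
        else:
            self.rho_hat = np.nan
            self.var_rho = np.nan
            self.var_log_rho = np.nan
            self.gamma_hat = np.nan
            self.var_gamma = np.nan

    @property
    def estimable(self) -> bool:
        """False when no diseased subject entered the base sample (n1 = 0);
        risks and relative risks are then unavailable, odds ratios remain."""
        return self.n1 > 0


@dataclass
class EffectEstimate:
    """A point estimate with a Wald interval on its transformed scale.

    ``transformed_point`` is the log OR, log RR or logit risk;
    ``point`` and the CI endpoints are back-transformed to the natural scale.
    """

    kind: str                     # "OR" | "RR" | "risk"
    point: float
    transformed_point: float
    se_transformed: float
    ci_low: float
    ci_high: float
    level: float = 0.95

    @property
    def transformed_ci(self) -> tuple[float, float]:
        z = norm.ppf(0.5 + self.level / 2.0)
        return (self.transformed_point - z * self.se_transformed,
                self.transformed_point + z * self.se_transformed)


@dataclass
class CaseBaseFit:
    """Complete case-base analysis: logistic fit, rho and corrected intercept."""

    logistic: LogisticFit
    rho: RhoGammaEstimate
    counts: SamplingCounts
    n_rows: int
    encoder: TermEncoder | None = None

    @property
    def columns(self) -> list[str]:
        return self.logistic.columns

    @property
    def alpha_star(self) -> float:
        return self.logistic.alpha_star

    @property
    def beta_hat(self) -> np.ndarray:
        return self.logistic.beta

    @property
    def alpha_hat(self) -> float:
        """Corrected population intercept alpha* + log rho_hat."""
        if not self.rho.estimable:
            return np.nan
        return self.logistic.alpha_star + np.log(self.rho.rho_hat)

    # conveniences mirroring the functional API
    def risk(self, x, level: float = 0.95) -> EffectEstimate:
        return estimate_risk(self, x, level=level)

    def relative_risk(self, x1, x0, level: float = 0.95) -> EffectEstimate:
        return estimate_rr(self, x1, x0, level=level)

    def odds_ratio(self, contrast, level: float = 0.95) -> EffectEstimate:
        return estimate_or(self, contrast, level=level)


# ---------------------------------------------------------------------------
# fitting
# ---------------------------------------------------------------------------

def _check_rank(X: np.ndarray, columns: Sequence[str]) -> None:
    if X.shape[0] < X.shape[1]:
        raise RankDeficientError(
            f"{X.shape[0]} rows cannot identify {X.shape[1]} parameters")
    r = np.linalg.matrix_rank(X)
    if r < X.shape[1]:
        # point at a culprit via the QR diagonal
        _, R = np.linalg.qr(X)
        diag = np.abs(np.diag(R))
        bad = [c for c, d in zip(columns, diag) if d < 1e-8 * max(diag.max(), 1.0)]
        raise RankDeficientError(
            f"design matrix is rank deficient (rank {r} < {X.shape[1]}); "
            f"suspect columns: {bad or 'unknown'}")


def _fit_logistic_matrix(X: np.ndarray, endog: np.ndarray,
                         columns: Sequence[str],
                         tol: float = 1e-12,
                         max_iter: int = 200) -> LogisticFit:
    """IRLS logistic fit with intercept prepended; endog is 0/1 per row or a
    two-column (successes, failures) array for grouped data."""
    Xi = np.column_stack([np.ones(X.shape[0]), X])
    names = ["(intercept)", *columns]
    _check_rank(Xi, names)
    y = np.asarray(endog, dtype=float)
    if y.ndim == 1:
        n_dis = float(y.sum())
        n_tot = float(y.size)
    else:
        n_dis = float(y[:, 0].sum())
        n_tot = float(y.sum())
    if n_dis == 0 or n_dis == n_tot:
        raise SeparationError(
            "dataset needs at least one diseased and one non-diseased recruit")
    model = sm.GLM(y, Xi, family=sm.families.Binomial())
    try:
        import warnings as _warnings
        with _warnings.catch_warnings():
            # separation is re-detected below and raised as SeparationError
            _warnings.simplefilter("ignore")
            res = model.fit(maxiter=max_iter, tol=tol)
    except Exception as exc:  # statsmodels PerfectSeparationError etc.
        if "separation" in str(exc).lower():
            raise SeparationError(str(exc)) from exc
        raise
    params = np.asarray(res.params, dtype=float)
    # polish with a few Newton steps: IRLS stops on the deviance, which
    # leaves ~sqrt(tol) slack in the parameters; downstream algebraic
    # identities (e.g. the closed-form single-exposure specialization)
    # hold to machine precision only at the exact optimum
    if y.ndim == 1:
        succ, tot = y, np.ones_like(y)
    else:
        succ, tot = y[:, 0], y.sum(axis=1)
    cov = None
    if np.isfinite(params).all():
        for _ in range(10):
            mu = expit(Xi @ params)
            w = tot * mu * (1.0 - mu)
            grad = Xi.T @ (succ - tot * mu)
            H = (Xi * w[:, None]).T @ Xi
            try:
                step = np.linalg.solve(H, grad)
            except np.linalg.LinAlgError:
                break
            params = params + step
            if np.abs(step).max() < 1e-13:
                cov = np.linalg.inv(H)
                break
    if not np.isfinite(params).all() or np.abs(params[1:]).max(initial=0.0) > _SEPARATION_BOUND:
        j = int(np.nanargmax(np.abs(params)))
        raise SeparationError(
            f"coefficient for {names[j]!r} diverged (|{params[j]:.1f}| > "
            f"{_SEPARATION_BOUND:g}); complete or quasi-complete separation")
    if cov is None:
        cov = np.asarray(res.cov_params(), dtype=float)
    return LogisticFit(alpha_star=float(params[0]), beta=params[1:],
                       covariance=cov, columns=list(columns),
                       converged=bool(res.converged),
                       n_iter=int(getattr(res, "fit_history", {}).get(
                           "iteration", max_iter)))


def fit_sample_logistic(dataset: pd.DataFrame,
                        terms: Sequence[str],
                        tol: float = 1e-12,
                        max_iter: int = 200) -> LogisticFit:
    """Fit the sample logistic model (disease on covariates) to a dataset.

    The dependent variable is the 0/1 disease status of every distinct
    recruited subject, regardless of the recruitment route. ``terms`` name
    dataset columns, dummy expansions ``"C(col)"`` or products ``"a:b"``.
    """
    validate_dataset(dataset)
    X, enc = build_matrix(dataset, terms)
    return _fit_logistic_matrix(
        X, dataset["disease"].to_numpy(dtype=float), columns=enc.columns,
        tol=tol, max_iter=max_iter)


def estimate_rho_gamma(counts: SamplingCounts) -> RhoGammaEstimate:
    """Maximum-likelihood estimates of rho and gamma from the counts."""
    return RhoGammaEstimate(n_D=counts.n_D, n1=counts.n1, n11=counts.n11)


def fit_casebase(dataset: pd.DataFrame,
                 terms: Sequence[str],
                 tol: float = 1e-12,
                 max_iter: int = 200) -> CaseBaseFit:
    """Full case-base analysis of a dataset: logistic fit + intercept correction."""
    validate_dataset(dataset)
    counts = tabulate_counts(dataset)
    X, enc = build_matrix(dataset, terms)
    logistic = _fit_logistic_matrix(
        X, dataset["disease"].to_numpy(dtype=float), columns=enc.columns,
        tol=tol, max_iter=max_iter)
    rho = estimate_rho_gamma(counts)
    return CaseBaseFit(logistic=logistic, rho=rho, counts=counts,
                       n_rows=len(dataset), encoder=enc)


# ---------------------------------------------------------------------------
# effect estimates
# ---------------------------------------------------------------------------

def _encode_profile(fit: CaseBaseFit, x) -> np.ndarray:
    if isinstance(x, dict):
        if fit.encoder is None:
            raise ValidationError(
                "this fit was built from a numeric matrix; pass an encoded "
                "covariate vector rather than a dict")
        v = fit.encoder.encode(x)
        if v.shape[0] != 1:
            raise ValidationError("profile dict must describe a single row")
        return v[0]
    v = np.asarray(x, dtype=float).ravel()
    if v.size != len(fit.columns):
        raise ValidationError(
            f"profile has {v.size} values, model has columns {fit.columns}")
    return v


def _require_rho(fit: CaseBaseFit) -> None:
    if not fit.rho.estimable:
        raise NotEstimableError(
            "no diseased subject was recruited in the base sample (n1 = 0): "
            "rho, absolute risks and relative risks are not estimable; "
            "odds ratios remain available")


def _wald(kind: str, transformed: float, var: float, level: float,
          back) -> EffectEstimate:
    se = float(np.sqrt(max(var, 0.0)))
    z = norm.ppf(0.5 + level / 2.0)
    lo, hi = transformed - z * se, transformed + z * se
    return EffectEstimate(kind=kind, point=float(back(transformed)),
                          transformed_point=float(transformed),
                          se_transformed=se, ci_low=float(back(lo)),
                          ci_high=float(back(hi)), level=level)


def estimate_risk(fit: CaseBaseFit, x, level: float = 0.95) -> EffectEstimate:
    """Absolute disease risk for profile x, with a logit-scale Wald CI."""
    _require_rho(fit)
    v = _encode_profile(fit, x)
    z_vec = np.concatenate([[1.0], v])
    l = fit.alpha_hat + v @ fit.beta_hat
    var = z_vec @ fit.logistic.covariance @ z_vec + fit.rho.var_log_rho
    return _wald("risk", l, var, level, expit)


def estimate_rr(fit: CaseBaseFit, x1, x0, level: float = 0.95) -> EffectEstimate:
    """Relative risk of profile x1 versus x0, with a log-scale Wald CI."""
    _require_rho(fit)
    v1 = _encode_profile(fit, x1)
    v0 = _encode_profile(fit, x0)
    if np.array_equal(v1, v0):
        return EffectEstimate(kind="RR", point=1.0, transformed_point=0.0,
                              se_transformed=0.0, ci_low=1.0, ci_high=1.0,
                              level=level)
    l1 = fit.alpha_hat + v1 @ fit.beta_hat
    l0 = fit.alpha_hat + v0 @ fit.beta_hat
    p1, p0 = expit(l1), expit(l0)
    log_rr = np.log(p1) - np.log(p0)
    c = (1.0 - p1) - (1.0 - p0)
    h = np.concatenate([[c], (1.0 - p1) * v1 - (1.0 - p0) * v0])
    var = h @ fit.logistic.covariance @ h + c * c * fit.rho.var_log_rho
    return _wald("RR", log_rr, var, level, np.exp)


def estimate_or(fit: CaseBaseFit | LogisticFit, contrast,
                level: float = 0.95) -> EffectEstimate:
    """Odds ratio exp(contrast . beta); valid even when rho is not estimable."""
    logistic = fit.logistic if isinstance(fit, CaseBaseFit) else fit
    if isinstance(contrast, str):
        if contrast not in logistic.columns:
            raise ValidationError(
                f"unknown column {contrast!r}; model columns: {logistic.columns}")
        c = np.zeros(len(logistic.columns))
        c[logistic.columns.index(contrast)] = 1.0
    else:
        c = np.asarray(contrast, dtype=float).ravel()
        if c.size != len(logistic.columns):
            raise ValidationError(
                f"contrast has {c.size} entries, model has columns "
                f"{logistic.columns}")
    log_or = c @ logistic.beta
    var = c @ logistic.covariance[1:, 1:] @ c
    return _wald("OR", log_or, var, level, np.exp)


# ---------------------------------------------------------------------------
# scikit-learn style estimator
# ---------------------------------------------------------------------------

class CaseBaseRegression(BaseEstimator):
    """Intercept-corrected logistic regression for case-base samples.

    Fits the logistic disease model to the recruited subjects and corrects
    the intercept with log(n1 / n_D) so that ``predict_proba`` returns
    *population* absolute risks rather than within-sample disease fractions.
    With no sampling flags supplied the data are treated as a cohort
    (rho = 1) and the model coincides with ordinary logistic regression.

    Parameters
    ----------
    level : float, default 0.95
        Confidence level for Wald intervals.
    tol : float, default 1e-12
        IRLS convergence tolerance.
    max_iter : int, default 200
        Maximum IRLS iterations.

    Attributes
    ----------
    coef_ : ndarray of shape (p,)
        Log odds ratios.
    intercept_ : float
        Corrected population intercept alpha_hat (NaN when n1 = 0).
    alpha_star_ : float
        Uncorrected sample intercept.
    rho_, gamma_ : float
        Sampling-parameter estimates (gamma_ may be NaN).
    covariance_ : ndarray of shape (1+p, 1+p)
        Covariance of (alpha*, beta).
    var_log_rho_ : float
        Delta-method variance of log rho_hat.
    n_D_, n1_, n11_ : int
        Recruited-diseased counts.

    Examples
    --------
    >>> est = CaseBaseRegression().fit(X, y, in_case_sample=sc, in_base_sample=sb)
    >>> est.relative_risk([1.0], [0.0]).point
    """

    def __init__(self, level: float = 0.95, tol: float = 1e-12,
                 max_iter: int = 200) -> None:
        self.level = level
        self.tol = tol
        self.max_iter = max_iter

    def fit(self, X, y, in_case_sample=None, in_base_sample=None):
        X, y = check_X_y(X, y, dtype=float, ensure_min_samples=2)
        if not np.isin(y, (0, 1)).all():
            raise ValidationError("y must be 0/1 disease indicators")
        n = X.shape[0]
        if in_case_sample is None and in_base_sample is None:
            in_case = np.zeros(n, dtype=int)
            in_base = np.ones(n, dtype=int)
        else:
            if in_case_sample is None or in_base_sample is None:
                raise ValidationError(
                    "pass both sampling flags, or neither for cohort data")
            in_case = np.asarray(in_case_sample, dtype=int).ravel()
            in_base = np.asarray(in_base_sample, dtype=int).ravel()
        frame = pd.DataFrame({"disease": y.astype(int),
                              "in_case_sample": in_case,
                              "in_base_sample": in_base})
        counts = tabulate_counts(frame)
        columns = [f"x{i}" for i in range(X.shape[1])]
        logistic = _fit_logistic_matrix(X, y, columns=columns,
                                        tol=self.tol, max_iter=self.max_iter)
        rho = estimate_rho_gamma(counts)
        self.result_ = CaseBaseFit(logistic=logistic, rho=rho, counts=counts,
                                   n_rows=n, encoder=None)
        self.n_features_in_ = X.shape[1]
        self.coef_ = logistic.beta
        self.alpha_star_ = logistic.alpha_star
        self.intercept_ = self.result_.alpha_hat
        self.rho_ = rho.rho_hat
        self.gamma_ = rho.gamma_hat
        self.var_log_rho_ = rho.var_log_rho
        self.covariance_ = logistic.covariance
        self.n_D_, self.n1_, self.n11_ = counts.n_D, counts.n1, counts.n11
        self.converged_ = logistic.converged
        self.classes_ = np.array([0, 1])
        return self

    def predict_proba(self, X) -> np.ndarray:
        """Population disease risk per row, as an (n, 2) class-probability array."""
        check_is_fitted(self, "result_")
        _require_rho(self.result_)
        X = check_array(X, dtype=float)
        p = expit(self.intercept_ + X @ self.coef_)
        return np.column_stack([1.0 - p, p])

    def predict(self, X) -> np.ndarray:
        return (self.predict_proba(X)[:, 1] >= 0.5).astype(int)

    def risk(self, x) -> EffectEstimate:
        check_is_fitted(self, "result_")
        return estimate_risk(self.result_, x, level=self.level)

    def relative_risk(self, x1, x0) -> EffectEstimate:
        check_is_fitted(self, "result_")
        return estimate_rr(self.result_, x1, x0, level=self.level)

    def odds_ratio(self, contrast) -> EffectEstimate:
        check_is_fitted(self, "result_")
        return estimate_or(self.result_, contrast, level=self.level)
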