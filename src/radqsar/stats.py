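"""Ordinary least squares QSAR regression and its diagnostics suite.

Implements the statistics used to judge a low-data QSAR model: the sums of
squares (RSS residual, TSS total, ESS explained), the coefficient of
determination R^2 = ESS/TSS, the significance-of-regression F statistic
F = (ESS/(p-1)) / (RSS/(n-p)) with its 95% critical value from the
F(p-1, n-p) distribution, the leave-one-out PRESS with its cross-validated
R^2(CV) = 1 - PRESS/TSS, and the RMSE with divisor N.

The estimator :class:`LinearQsarRegressor` follows the scikit-learn API
(fit/predict, ``coef_``/``intercept_`` attributes) and always includes an
intercept; :func:`fit_ols` is a thin functional wrapper returning an
:class:`MlrModel` record suitable for reporting and screening.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps
from sklearn.base import BaseEstimator, RegressorMixin

from .data import DataSet
from .errors import (
    AlignmentError,
    DegenerateInputError,
    DegreesOfFreedomError,
    SingularityError,
)

__all__ = [
    "MlrModel", "RegressionStats", "LinearQsarRegressor", "fit_ols",
    "predict_linear", "sum_of_squares", "r_squared", "f_statistic",
    "f_critical", "loo_press", "r2_cv", "rmse", "pearson_matrix",
    "regression_report",
]

#: Tolerance used when verifying the TSS = ESS + RSS identity.
IDENTITY_RTOL = 1e-9


@dataclass(frozen=True)
class MlrModel:
    """A fitted (or published) multiple linear regression model.

    ``predict`` evaluates intercept + sum(coefficient * descriptor)."""

    descriptor_ids: tuple[str, ...]
    coefficients: tuple[float, ...]
    intercept: float
    response_id: str = "Y1"

    def __post_init__(self) -> None:
        if len(set(self.descriptor_ids)) != len(self.descriptor_ids):
            raise AlignmentError("descriptor ids in a model must be distinct")
        if not np.isfinite(list(self.coefficients) + [self.intercept]).all():
            raise SingularityError("non-finite model coefficients")

    def predict(self, X) -> np.ndarray:
        return predict_linear(self, X)


@dataclass(frozen=True)
class RegressionStats:
    """The full diagnostics block for one model on one data set.

    ``press``/``r2_cv``/``f``/``f_critical`` are None when they do not apply
    (e.g. test-set evaluation of a fixed model, or network predictions)."""

    n: int
    p: int
    rss: float
    tss: float
    ess: float
    r2: float
    rmse: float
    f: float | None = None
    f_critical: float | None = None
    press: float | None = None
    r2_cv: float | None = None


def _as_matrix(X) -> tuple[np.ndarray, list[str]]:
    if isinstance(X, pd.DataFrame):
        return X.to_numpy(dtype=float), [str(c) for c in X.columns]
    X = np.asarray(X, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    return X, [f"x{j}" for j in range(X.shape[1])]


def _collinear_columns(design: np.ndarray, names: list[str]) -> list[str]:
    # QR with column pivoting: pivots beyond the numerical rank name the
    # columns that are linear combinations of earlier ones.
    from scipy.linalg import qr

    _, R, piv = qr(design, mode="economic", pivoting=True)
    diag = np.abs(np.diag(R))
    tol = diag.max() * max(design.shape) * np.finfo(float).eps
    rank = int((diag > tol).sum())
    return [names[j] for j in sorted(piv[rank:])]


class LinearQsarRegressor(BaseEstimator, RegressorMixin):
    """OLS regression with an always-included intercept and QSAR diagnostics.

    Parameters
    ----------
    alpha : float, default 0.05
        Significance level for the critical F value.
    compute_press : bool, default True
        Whether to run the leave-one-out refits for PRESS/R^2(CV) during
        :meth:`fit`. The GA search disables this (its fitness is plain R^2)
        and computes PRESS only for models that are reported.

    Attributes (after :meth:`fit`)
    ------------------------------
    coef_ : ndarray of shape (p-1,)
    intercept_ : float
    feature_names_in_ : list of str
    stats_ : :class:`RegressionStats`
        Training diagnostics including PRESS/R^2(CV) when n > p + 1.
    """

    def __init__(self, alpha: float = 0.05, compute_press: bool = True):
        self.alpha = alpha
        self.compute_press = compute_press

    def fit(self, X, y) -> "LinearQsarRegressor":
        M, names = _as_matrix(X)
        y = np.asarray(y, dtype=float).ravel()
        n, k = M.shape
        p = k + 1
        if y.shape[0] != n:
            raise AlignmentError(f"X has {n} rows but y has {y.shape[0]}")
        if n <= p:
            raise DegreesOfFreedomError(
                f"need n > p for OLS: n={n}, p={p} (incl. intercept)")
        design = np.column_stack([np.ones(n), M])
        rank = np.linalg.matrix_rank(design)
        if rank < p:
            bad = _collinear_columns(design, ["intercept"] + names)
            raise SingularityError(
                "rank-deficient design matrix; collinear column(s): "
                + ", ".join(bad))
        beta, *_ = np.linalg.lstsq(design, y, rcond=None)
        self.intercept_ = float(beta[0])
        self.coef_ = beta[1:]
        self.feature_names_in_ = names
        self.n_features_in_ = k
        fitted = design @ beta
        press = r2cv = None
        if self.compute_press and n > p + 1:
            press = loo_press(M, y)
            _, tss, _ = sum_of_squares(y, fitted)
            r2cv = r2_cv(press, tss)
        self.stats_ = regression_report(y, fitted, p=p, alpha=self.alpha,
                                        press=press, r2_cv_value=r2cv)
        return self

    def predict(self, X) -> np.ndarray:
        M, names = _as_matrix(X)
        if isinstance(X, pd.DataFrame):
            missing = [c for c in self.feature_names_in_ if c not in names]
            if missing:
                raise AlignmentError(
                    "missing descriptor column(s): " + ", ".join(missing))
            M = X[self.feature_names_in_].to_numpy(dtype=float)
        elif M.shape[1] != self.n_features_in_:
            raise AlignmentError(
                f"model expects {self.n_features_in_} columns, got {M.shape[1]}")
        return self.intercept_ + M @ self.coef_

    def to_mlr_model(self, response_id: str = "Y1") -> MlrModel:
        return MlrModel(tuple(self.feature_names_in_),
                        tuple(float(c) for c in self.coef_),
                        self.intercept_, response_id)


def fit_ols(ds: DataSet | pd.DataFrame, response, descriptor_ids=None,
            response_id: str = "Y1") -> tuple[MlrModel, RegressionStats]:
    """Fit an OLS model of one activity on a descriptor subset.

    Accepts either ``(DataSet, "Y1", [ids])`` or ``(X frame/array, y)``.
    Returns the coefficient record and its training diagnostics.
    """
    if isinstance(ds, DataSet):
        response_id = response
        y = ds.activities.response(response_id)
        X = pd.DataFrame(ds.descriptors.columns(list(descriptor_ids)),
                         columns=list(descriptor_ids))
    else:
        X, y = ds, np.asarray(response, dtype=float)
        if descriptor_ids is not None:
            X = pd.DataFrame(np.asarray(X), columns=list(descriptor_ids))
    est = LinearQsarRegressor().fit(X, y)
    return est.to_mlr_model(response_id), est.stats_


def predict_linear(model: MlrModel, X) -> np.ndarray:
    """Evaluate intercept + sum(coef * descriptor) over rows of ``X``.

    ``X`` may be a DataFrame or DescriptorTable (columns matched by id) or a
    plain array whose columns follow ``model.descriptor_ids``."""
    if hasattr(X, "columns") and callable(getattr(X, "columns", None)):
        M = X.columns(list(model.descriptor_ids))  # DescriptorTable
    elif isinstance(X, pd.DataFrame):
        missing = [c for c in model.descriptor_ids if c not in X.columns]
        if missing:
            raise AlignmentError(
                "missing descriptor column(s): " + ", ".join(missing))
        M = X[list(model.descriptor_ids)].to_numpy(dtype=float)
    else:
        M = np.asarray(X, dtype=float)
        if M.ndim == 1:
            M = M[None, :]
        if M.shape[1] != len(model.descriptor_ids):
            raise AlignmentError(
                f"model expects {len(model.descriptor_ids)} columns, "
                f"got {M.shape[1]}")
    return model.intercept + M @ np.asarray(model.coefficients)


# ---------------------------------------------------------------------------
# statistics primitives

def sum_of_squares(y, yhat) -> tuple[float, float, float]:
    """Return (RSS, TSS, ESS): residual, total and explained sums of squares.

    For an OLS fit with intercept, TSS = ESS + RSS holds to rounding."""
    y = np.asarray(y, dtype=float).ravel()
    yhat = np.asarray(yhat, dtype=float).ravel()
    if y.shape != yhat.shape:
        raise AlignmentError("observed and fitted vectors differ in length")
    if y.size < 2:
        raise DegenerateInputError("need at least 2 observations")
    ybar = y.mean()
    rss = float(np.sum((yhat - y) ** 2))
    tss = float(np.sum((y - ybar) ** 2))
    ess = float(np.sum((yhat - ybar) ** 2))
    return rss, tss, ess


def r_squared(ess: float, tss: float) -> float:
    """R^2 = ESS / TSS (equals 1 - RSS/TSS for intercept OLS)."""
    if tss <= 0:
        raise DegenerateInputError("zero total sum of squares (constant response)")
    return ess / tss


def f_statistic(rss: float, ess: float, n: int, p: int) -> float:
    """Significance-of-regression F = (ESS/(p-1)) / (RSS/(n-p)).

    A perfect fit (zero RSS) returns +inf with a warning rather than raising."""
    if n <= p:
        raise DegreesOfFreedomError(f"F undefined for n={n} <= p={p}")
    if p < 2:
        raise DegreesOfFreedomError("F needs at least one regressor (p >= 2)")
    ms_explained = ess / (p - 1)
    ms_residual = rss / (n - p)
    if ms_residual == 0.0:
        warnings.warn("perfect fit: zero residual mean square, F reported as "
                      "inf", UserWarning, stacklevel=2)
        return float("inf") if ms_explained > 0 else 0.0
    return ms_explained / ms_residual


def f_critical(p: int, n: int, alpha: float = 0.05) -> float:
    """Upper-alpha quantile of F with (p-1, n-p) degrees of freedom."""
    if n <= p or p < 2:
        raise DegreesOfFreedomError(f"F critical undefined for n={n}, p={p}")
    return float(sps.f.ppf(1.0 - alpha, p - 1, n - p))


def loo_press(X, y) -> float:
    """Leave-one-out PRESS by explicit refitting.

    Each observation is removed in turn, the OLS model is refit on the rest
    and the held-out response predicted; PRESS is the sum of squared
    prediction errors. (Equals the hat-matrix closed form
    sum((e_i / (1 - h_ii))^2) for OLS, which the tests use as an independent
    check.)"""
    M, _ = _as_matrix(X)
    y = np.asarray(y, dtype=float).ravel()
    n, k = M.shape
    p = k + 1
    if n < p + 1:
        raise DegreesOfFreedomError(
            f"PRESS needs n >= p + 1 so every leave-one-out fit is "
            f"determined: n={n}, p={p}")
    press = 0.0
    for i in range(n):
        keep = np.ones(n, dtype=bool)
        keep[i] = False
        design = np.column_stack([np.ones(n - 1), M[keep]])
        if np.linalg.matrix_rank(design) < p:
            raise SingularityError(
                f"leave-one-out fit without observation {i} is singular")
        beta, *_ = np.linalg.lstsq(design, y[keep], rcond=None)
        pred = beta[0] + M[i] @ beta[1:]
        press += (y[i] - pred) ** 2
    return float(press)


def r2_cv(press: float, tss: float) -> float:
    """Cross-validated R^2(CV) = 1 - PRESS/TSS; negative for hopeless models."""
    if tss <= 0:
        raise DegenerateInputError("zero total sum of squares")
    return 1.0 - press / tss


def rmse(y, yhat) -> float:
    """Root mean square error, divisor = number of observations."""
    y = np.asarray(y, dtype=float).ravel()
    yhat = np.asarray(yhat, dtype=float).ravel()
    if y.shape != yhat.shape:
        raise AlignmentError("observed and predicted vectors differ in length")
    return float(np.sqrt(np.mean((y - yhat) ** 2)))


def regression_report(y, yhat, p: int, alpha: float = 0.05,
                      press: float | None = None,
                      r2_cv_value: float | None = None,
                      with_f: bool = True) -> RegressionStats:
    """Assemble a :class:`RegressionStats` block from observed/predicted values."""
    y = np.asarray(y, dtype=float).ravel()
    n = y.size
    rss_v, tss_v, ess_v = sum_of_squares(y, yhat)
    f_v = f_cr = None
    if with_f and n > p >= 2:
        f_v = f_statistic(rss_v, ess_v, n, p)
        f_cr = f_critical(p, n, alpha)
    return RegressionStats(n=n, p=p, rss=rss_v, tss=tss_v, ess=ess_v,
                           r2=r_squared(ess_v, tss_v), rmse=rmse(y, yhat),
                           f=f_v, f_critical=f_cr, press=press,
                           r2_cv=r2_cv_value)


def pearson_matrix(ds: DataSet) -> pd.DataFrame:
    """Pearson correlation matrix over all descriptors and the three
    activities (the screening heatmap's contents). Zero-variance columns give
    NaN entries -- flagged undefined rather than silently zero."""
    frame = ds.descriptors.to_frame().join(ds.activities.to_frame())
    constant = [c for c in frame.columns if frame[c].std(ddof=0) == 0]
    if constant:
        warnings.warn("zero-variance column(s) give undefined correlations: "
                      + ", ".join(map(str, constant)), UserWarning, stacklevel=2)
    return frame.corr(method="pearson")
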