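"""Ordinary least squares with explicit model-matrix algebra.

The substitution estimands downstream are differences between model
predictions at two design rows, so the fit object keeps exactly what that
contrast needs: the coefficient vector, the inverse cross-product matrix
``(X'X)^-1``, the residual standard error and its degrees of freedom.  A
prediction-difference interval for rows ``x1`` and ``x0`` is

    d'beta  +/-  t_{df, (1+level)/2} * s * sqrt( d' (X'X)^-1 d ),   d = x1 - x0,

which makes covariate columns shared by both rows cancel exactly.

``diagnostics`` bundles the usual battery for a fitted linear model: Ramsey
RESET for functional form, variance inflation factors for collinearity,
Durbin-Watson for residual autocorrelation, Breusch-Pagan for
heteroscedasticity and Shapiro-Wilk for residual normality.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import scipy.linalg
from scipy import stats

__all__ = [
    "FittedModel",
    "PredictionCI",
    "SingularDesignError",
    "fit_ols",
    "predict_difference_ci",
    "coefficient_ci",
    "diagnostics",
]


class SingularDesignError(ValueError):
    """Design matrix is rank deficient; names the offending columns."""


@dataclass(frozen=True)
class PredictionCI:
    estimate: float
    lower: float
    upper: float
    level: float = 0.95

    def __post_init__(self):
        if not (self.lower <= self.estimate <= self.upper):
            raise ValueError("interval must bracket the estimate")

    @property
    def significant(self) -> bool:
        """Whether the interval excludes zero."""
        return self.lower > 0 or self.upper < 0


@dataclass(frozen=True)
class FittedModel:
    """OLS fit: coefficients plus the pieces needed for prediction CIs."""

    beta: np.ndarray
    xtx_inv: np.ndarray
    resid_se: float
    df: int
    columns: tuple[str, ...]
    n: int

    def predict(self, row) -> float:
        row = np.asarray(row, dtype=float)
        return float(row @ self.beta)

    def column_index(self, name: str) -> int:
        try:
            return self.columns.index(name)
        except ValueError:
            raise KeyError(f"no column {name!r} in {self.columns}") from None


def _as_design(X, columns):
    X = np.asarray(X, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    n, p = X.shape
    if columns is None:
        columns = tuple(f"x{j}" for j in range(p))
    else:
        columns = tuple(columns)
        if len(columns) != p:
            raise ValueError("number of column names does not match design matrix")
    return X, columns, n, p


def fit_ols(X, y, columns=None) -> FittedModel:
    """Fit ``y = X beta + e`` by least squares via the normal equations.

    Raises :class:`SingularDesignError` naming the collinear columns when the
    design is rank deficient, and ``ValueError`` when there are not more rows
    than columns.
    """
    X, columns, n, p = _as_design(X, columns)
    y = np.asarray(y, dtype=float).ravel()
    if y.shape[0] != n:
        raise ValueError("X and y have different numbers of rows")
    if n <= p:
        raise ValueError(f"need more observations ({n}) than parameters ({p})")
    rank = np.linalg.matrix_rank(X)
    if rank < p:
        # QR with column pivoting puts the dependent columns last.
        _, _, piv = scipy.linalg.qr(X, mode="economic", pivoting=True)
        bad = sorted(columns[j] for j in piv[rank:])
        raise SingularDesignError(f"design matrix is rank deficient; collinear columns: {bad}")
    xtx_inv = np.linalg.inv(X.T @ X)
    beta = xtx_inv @ (X.T @ y)
    resid = y - X @ beta
    df = n - p
    s = float(np.sqrt(max(resid @ resid, 0.0) / df))
    return FittedModel(beta=beta, xtx_inv=xtx_inv, resid_se=s, df=df, columns=columns, n=n)


def predict_difference_ci(fit: FittedModel, x1, x0, level: float = 0.95) -> PredictionCI:
    """CI for the difference in mean predictions between design rows x1 and x0.

    Uses the residual standard error, the model-matrix cross-product inverse
    and the two-sided critical value of the t distribution on the residual
    degrees of freedom.  Columns identical in both rows cancel exactly.
    """
    if not 0 < level < 1:
        raise ValueError("confidence level must be in (0, 1)")
    x1 = np.asarray(x1, dtype=float).ravel()
    x0 = np.asarray(x0, dtype=float).ravel()
    if x1.shape != x0.shape or x1.shape[0] != len(fit.columns):
        raise ValueError("design rows do not conform to the fitted columns")
    d = x1 - x0
    estimate = float(d @ fit.beta)
    se = fit.resid_se * float(np.sqrt(max(d @ fit.xtx_inv @ d, 0.0)))
    half = float(stats.t.ppf(0.5 + level / 2, fit.df)) * se
    return PredictionCI(estimate=estimate, lower=estimate - half, upper=estimate + half, level=level)


def coefficient_ci(fit: FittedModel, column: int | str, level: float = 0.95) -> PredictionCI:
    """CI for a single coefficient, as a unit-difference prediction contrast."""
    j = fit.column_index(column) if isinstance(column, str) else int(column)
    p = len(fit.columns)
    x1 = np.zeros(p)
    x1[j] = 1.0
    return predict_difference_ci(fit, x1, np.zeros(p), level=level)


def _has_intercept(X) -> bool:
    return bool(np.any(np.all(np.isclose(X, X[0:1, :]), axis=0)))


def diagnostics(fit: FittedModel, X, y) -> dict:
    """Regression diagnostic battery for a fit produced from ``(X, y)``.

    Returns a dict with RESET p value (powers 2-3 of the fitted values,
    F test), per-column VIF (constant columns skipped), the Durbin-Watson
    statistic, the Breusch-Pagan LM p value and the Shapiro-Wilk W and p on
    the residuals.  Entries a given sample is too small to support are
    reported as ``None`` rather than raising.
    """
    import statsmodels.api as sm
    from statsmodels.stats.diagnostic import het_breuschpagan, linear_reset
    from statsmodels.stats.outliers_influence import variance_inflation_factor
    from statsmodels.stats.stattools import durbin_watson

    X, columns, n, p = _as_design(X, fit.columns)
    y = np.asarray(y, dtype=float).ravel()
    resid = y - X @ fit.beta
    report: dict = {"n": n}

    try:
        with warnings.catch_warnings(), np.errstate(all="ignore"):
            warnings.simplefilter("ignore")  # degenerate small-n fits
            res = sm.OLS(y, X).fit()
            stat = linear_reset(res, power=3, test_type="fitted", use_f=True)
            report["reset_p"] = float(stat.pvalue)
        if not np.isfinite(report["reset_p"]):
            report["reset_p"] = None
    except Exception:
        report["reset_p"] = None

    vif = {}
    constant = [np.isclose(np.var(X[:, j]), 0.0) for j in range(p)]
    for j, name in enumerate(columns):
        if constant[j]:
            continue
        try:
            vif[name] = float(variance_inflation_factor(X, j))
        except Exception:
            vif[name] = None
    report["vif"] = vif

    report["durbin_watson"] = float(durbin_watson(resid)) if n >= 2 else None

    try:
        _, bp_p, _, _ = het_breuschpagan(resid, X if _has_intercept(X) else sm.add_constant(X))
        report["breusch_pagan_p"] = float(bp_p)
    except Exception:
        report["breusch_pagan_p"] = None

    if n >= 3:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")  # large-n p-value accuracy warning
            w, sp = stats.shapiro(resid)
        report["shapiro_w"], report["shapiro_p"] = float(w), float(sp)
    else:
        report["shapiro_w"] = report["shapiro_p"] = None
    return report
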