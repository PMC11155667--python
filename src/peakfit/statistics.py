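"""Fit-quality statistics: the six-table report and the metric ledger.

Covers descriptive statistics of the input data, chi-square-based fit
statistics with AIC/BIC, Pearson correlation between data / fit /
residual / components, scikit-learn regression metrics, a linear trend
through the residual with a t-distribution confidence band, and an
iteration-by-iteration metric ledger for model refinement.

AIC and BIC use the least-squares log-likelihood form
``N * ln(chi2 / N)`` plus their respective penalties, the convention of
common least-squares fitting backends, so the two always satisfy
``bic - aic = k * (ln N - 2)``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Any, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps
from sklearn import metrics as skm

from .config import Spectrum
from .exceptions import DegreesOfFreedomError, InputValidationError, PeakfitError

__all__ = [
    "GoodnessOfFit", "RegressionMetrics", "CorrelationMatrix", "MetricLedger",
    "descriptive", "correlation_matrix", "goodness_of_fit",
    "regression_metrics", "residual_trend", "six_tables",
]

#: chi2 is floored here before the logarithm in AIC/BIC (sentinel for a
#: numerically perfect fit).
CHI2_FLOOR = 1e-250


@dataclass(frozen=True)
class GoodnessOfFit:
    """Chi-square family of fit statistics."""

    chi2: float
    red_chi2: float
    aic: float
    bic: float
    n_points: int
    n_free: int

    def as_dict(self) -> dict[str, float]:
        return {"chi2": self.chi2, "red_chi2": self.red_chi2,
                "aic": self.aic, "bic": self.bic,
                "n_points": self.n_points, "n_free": self.n_free}


@dataclass(frozen=True)
class RegressionMetrics:
    """scikit-learn style regression scores of data vs. fitted curve."""

    mae: float
    mse: float
    rmse: float
    r2: float
    evs: float
    defined: bool = True  # False when var(y) == 0 makes r2/evs meaningless

    def as_dict(self) -> dict[str, float]:
        return {"mae": self.mae, "mse": self.mse, "rmse": self.rmse,
                "r2": self.r2, "evs": self.evs}


def goodness_of_fit(residual, k: int) -> GoodnessOfFit:
    """Chi-square, reduced chi-square, AIC and BIC from a residual vector.

    ``chi2`` is the plain (unweighted) residual sum of squares; ``k`` is
    the number of free parameters.
    """
    r = np.asarray(residual, dtype=float)
    n = r.size
    if k < 0:
        raise DegreesOfFreedomError(f"negative free-parameter count {k}")
    if n <= k:
        raise DegreesOfFreedomError(
            f"{n} point(s) with {k} free parameter(s): no degrees of freedom")
    chi2 = float(r @ r)
    red_chi2 = chi2 / (n - k)
    floored = max(chi2, CHI2_FLOOR)
    aic = n * math.log(floored / n) + 2 * k
    bic = n * math.log(floored / n) + k * math.log(n)
    return GoodnessOfFit(chi2=chi2, red_chi2=red_chi2, aic=aic, bic=bic,
                         n_points=n, n_free=k)


def regression_metrics(y, yhat) -> RegressionMetrics:
    """MAE, MSE, RMSE, R² and explained-variance score of a prediction.

    R² uses raw sums of squares and so penalizes a systematic offset;
    EVS uses the (biased) residual variance and is offset-blind, hence
    always ``evs >= r2``.
    """
    y = np.asarray(y, dtype=float)
    yhat = np.asarray(yhat, dtype=float)
    if y.shape != yhat.shape or y.ndim != 1:
        raise InputValidationError("y and yhat must be equal-length vectors")
    if y.size < 2:
        raise InputValidationError("need at least 2 points for regression metrics")
    mae = float(skm.mean_absolute_error(y, yhat))
    mse = float(skm.mean_squared_error(y, yhat))
    rmse = math.sqrt(mse)
    if np.var(y) == 0.0:
        return RegressionMetrics(mae=mae, mse=mse, rmse=rmse,
                                 r2=math.nan, evs=math.nan, defined=False)
    r2 = float(skm.r2_score(y, yhat))
    evs = float(skm.explained_variance_score(y, yhat))
    return RegressionMetrics(mae=mae, mse=mse, rmse=rmse, r2=r2, evs=evs)


def descriptive(s: Spectrum) -> pd.DataFrame:
    """Descriptive statistics of a spectrum: count, mean, sd, min, max and
    quantiles in 10% steps, per column."""
    frame = s.to_frame()
    if frame.empty:
        raise InputValidationError("empty spectrum")
    return frame.describe(percentiles=np.round(np.arange(0.1, 1.0, 0.1), 1))


@dataclass(frozen=True)
class CorrelationMatrix:
    """Labeled Pearson correlation matrix with explicit undefined pairs."""

    matrix: pd.DataFrame
    undefined: tuple[tuple[str, str], ...] = ()

    @property
    def labels(self) -> list[str]:
        return list(self.matrix.columns)


def correlation_matrix(series: dict[str, Any]) -> CorrelationMatrix:
    """Pearson correlation over a mapping of equal-length named series.

    Pairs involving a zero-variance series are *flagged* as undefined
    (NaN in the matrix) rather than silently reported as zero.
    """
    if not series:
        raise InputValidationError("no series given")
    arrays = {k: np.asarray(v, dtype=float) for k, v in series.items()}
    lengths = {a.size for a in arrays.values()}
    if len(lengths) != 1:
        raise InputValidationError(f"series lengths differ: {sorted(lengths)}")
    n = lengths.pop()
    if n < 3:
        raise InputValidationError("need at least 3 points for correlation")
    frame = pd.DataFrame(arrays)
    corr = frame.corr(method="pearson")
    degenerate = [k for k, a in arrays.items() if np.ptp(a) == 0.0]
    undefined = []
    for d in degenerate:
        for other in frame.columns:
            corr.loc[d, other] = np.nan
            corr.loc[other, d] = np.nan
            undefined.append(tuple(sorted((d, other))))
    np.fill_diagonal(corr.values, 1.0)
    return CorrelationMatrix(matrix=corr, undefined=tuple(sorted(set(undefined))))


@dataclass(frozen=True)
class ResidualTrend:
    """OLS line through the residual with a pointwise confidence band."""

    slope: float
    intercept: float
    confidence: float
    x: np.ndarray
    line: np.ndarray
    band_lower: np.ndarray
    band_upper: np.ndarray


def residual_trend(x, residual, conf: float = 0.95) -> ResidualTrend:
    """Fit an ordinary least-squares line through ``(x, residual)``.

    The band is the pointwise confidence interval of the regression mean
    from the t-distribution at the given level; a perfectly explained
    residual yields a zero-width band.
    """
    x = np.asarray(x, dtype=float)
    r = np.asarray(residual, dtype=float)
    if x.size != r.size or x.size < 3:
        raise InputValidationError("need >= 3 matching points for a residual trend")
    if np.ptp(x) == 0.0:
        raise InputValidationError("constant abscissa: trend undefined")
    res = sps.linregress(x, r)
    line = res.slope * x + res.intercept
    dof = x.size - 2
    resid = r - line
    s2 = float(resid @ resid) / dof if dof > 0 else 0.0
    sxx = float(np.sum((x - x.mean()) ** 2))
    se_mean = np.sqrt(s2 * (1.0 / x.size + (x - x.mean()) ** 2 / sxx))
    tval = sps.t.ppf(0.5 + conf / 2.0, dof)
    return ResidualTrend(slope=float(res.slope), intercept=float(res.intercept),
                         confidence=conf, x=x, line=line,
                         band_lower=line - tval * se_mean,
                         band_upper=line + tval * se_mean)


#: metric names accepted by the ledger → how to pull them from a result
_LEDGER_METRICS = ("aic", "bic", "chi2", "red_chi2",
                   "mae", "mse", "rmse", "r2", "evs")


@dataclass
class MetricLedger:
    """Ordered record of fit statistics across successive fit cycles.

    Default metric list is AIC, BIC and MSE (causality + accuracy); any
    of ``aic, bic, chi2, red_chi2, mae, mse, rmse, r2, evs`` may be
    configured instead.
    """

    metrics: Sequence[str] = ("aic", "bic", "mse")
    records: list[dict[str, float]] = field(default_factory=list)

    def __post_init__(self):
        if not self.metrics:
            raise InputValidationError("metric list must be nonempty")
        unknown = [m for m in self.metrics if m not in _LEDGER_METRICS]
        if unknown:
            raise InputValidationError(
                f"unknown metric(s) {unknown}; valid: {', '.join(_LEDGER_METRICS)}")

    def append(self, result) -> dict[str, float]:
        """Record one completed fit; returns the stored record."""
        pool = dict(result.gof.as_dict())
        if result.spectrum is not None:
            reg = regression_metrics(result.spectrum.y, result.model_curve)
            pool.update(reg.as_dict())
        try:
            record = {m: float(pool[m]) for m in self.metrics}
        except KeyError as exc:
            raise PeakfitError(
                f"metric {exc.args[0]!r} unavailable for this result") from exc
        self.records.append(record)
        return record

    def __len__(self) -> int:
        return len(self.records)

    def to_frame(self) -> pd.DataFrame:
        frame = pd.DataFrame(self.records, columns=list(self.metrics))
        frame.index.name = "fit_cycle"
        return frame


def metric_history(ledger: Optional[MetricLedger], result,
                   metrics: Optional[Sequence[str]] = None) -> MetricLedger:
    """Append ``result`` to ``ledger`` (created on first use)."""
    if ledger is None:
        ledger = MetricLedger(metrics=tuple(metrics) if metrics else ("aic", "bic", "mse"))
    ledger.append(result)
    return ledger


def six_tables(spectrum: Spectrum, result) -> dict[str, pd.DataFrame]:
    """The printable report: six tables in fixed order.

    Statistics | Fit Statistics | Variables and Values |
    Correlation of Component | Overall Linear-Correlation |
    Regression Metrics.
    """
    variables = pd.DataFrame(
        [{"parameter": p.name, "init_value": p.init_value, "best_value": p.value,
          "stderr_abs": p.stderr if p.stderr is not None else np.nan,
          "stderr_rel": (abs(p.stderr / p.value) if p.stderr and p.value
                         else np.nan),
          "vary": p.is_free, "expr": p.expr or ""}
         for p in result.params]).set_index("parameter")
    overall = {spectrum.x_label: spectrum.x, spectrum.y_label: spectrum.y,
               "fit": result.model_curve, "residual": result.residual,
               **result.components}
    overall_corr = correlation_matrix(overall)
    comp_labels = [c for c in overall if c != spectrum.x_label]
    component_corr = CorrelationMatrix(
        matrix=overall_corr.matrix.loc[comp_labels, comp_labels])
    reg = regression_metrics(spectrum.y, result.model_curve)
    return {
        "Statistics": descriptive(spectrum),
        "Fit Statistics": pd.DataFrame([result.gof.as_dict()]),
        "Variables and Values": variables,
        "Correlation of Component": component_corr.matrix,
        "Overall Linear-Correlation": overall_corr.matrix,
        "Regression Metrics": pd.DataFrame([reg.as_dict()]),
    }
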