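"""Deming (errors-in-both-variables) regression for method comparison.

Two quantitation methods measuring the same samples are compared by fitting
y = α + βx while allowing measurement error in both axes.  With the error
variance ratio δ = Var(ε_y)/Var(ε_x) fixed at 1 the fit reduces to
orthogonal least squares — the line minimising the sum of squared
perpendicular distances — with the closed form

    β = [s_yy − δ·s_xx + √((s_yy − δ·s_xx)² + 4δ·s_xy²)] / (2·s_xy)
    α = ȳ − β·x̄

where s_xx, s_yy, s_xy are the (co)variances of the paired measurements.
The positive root makes β share the sign of s_xy, which minimises (rather
than maximises) the orthogonal sum of squares.  Confidence intervals come
from a leave-one-out jackknife.  Agreement between methods is read off the
slope: a 95% CI containing 1 is flagged as agreement.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.stats
from sklearn.base import BaseEstimator, RegressorMixin
from sklearn.utils.validation import check_is_fitted

__all__ = ["PairedMeasurements", "DemingFit", "DemingRegressor", "deming_fit", "agreement_report"]

logger = logging.getLogger(__name__)


@dataclass
class PairedMeasurements:
    """Concentrations of the same (sample, target, dilution) by two methods.

    Incomplete pairs (NaN on either axis) are dropped with a log entry.
    """

    x: np.ndarray
    y: np.ndarray
    ids: list[tuple] | None = None

    def __post_init__(self) -> None:
        self.x = np.asarray(self.x, dtype=float)
        self.y = np.asarray(self.y, dtype=float)
        if self.x.shape != self.y.shape or self.x.ndim != 1:
            raise ValueError("x and y must be 1-D arrays of equal length")
        if self.ids is not None and len(self.ids) != self.x.size:
            raise ValueError("ids length must match x/y")
        ok = np.isfinite(self.x) & np.isfinite(self.y)
        if not ok.all():
            dropped = int((~ok).sum())
            logger.info("dropping %d incomplete measurement pair(s)", dropped)
            self.x, self.y = self.x[ok], self.y[ok]
            if self.ids is not None:
                self.ids = [i for i, keep in zip(self.ids, ok) if keep]
        if self.x.size < 3:
            raise ValueError("method comparison needs >= 3 complete pairs")


@dataclass(frozen=True)
class DemingFit:
    """Result of a Deming regression y = intercept + slope·x."""

    slope: float
    intercept: float
    variance_ratio: float
    n: int
    ci_slope: tuple[float, float] | None
    ci_intercept: tuple[float, float] | None


def _deming_closed_form(x: np.ndarray, y: np.ndarray, delta: float) -> tuple[float, float]:
    xbar, ybar = x.mean(), y.mean()
    sxx = float(np.sum((x - xbar) ** 2))
    syy = float(np.sum((y - ybar) ** 2))
    sxy = float(np.sum((x - xbar) * (y - ybar)))
    if sxy == 0.0:
        if syy == delta * sxx:
            raise ValueError("degenerate orientation: no covariance and equal variances")
        if syy > delta * sxx:
            raise ValueError("degenerate orientation: best orthogonal line is vertical")
        slope = 0.0
    else:
        d = syy - delta * sxx
        slope = (d + np.sqrt(d * d + 4.0 * delta * sxy * sxy)) / (2.0 * sxy)
    return slope, ybar - slope * xbar


class DemingRegressor(BaseEstimator, RegressorMixin):
    """Deming regression as a scikit-learn estimator.

    Parameters
    ----------
    variance_ratio : float, default 1.0
        δ = Var(error in y)/Var(error in x).  δ = 1 assumes equal error
        variance in both methods (orthogonal least squares).
    ci : bool, default True
        Compute 95% jackknife confidence intervals for slope and intercept.
        With fewer than 4 pairs the jackknife is unstable and the intervals
        are reported as missing.

    Attributes
    ----------
    slope_, intercept_ : float
    ci_slope_, ci_intercept_ : tuple or None
    n_ : int
    """

    def __init__(self, variance_ratio: float = 1.0, ci: bool = True):
        self.variance_ratio = variance_ratio
        self.ci = ci

    def fit(self, X, y):
        if not self.variance_ratio > 0:
            raise ValueError("variance_ratio must be > 0")
        x = np.asarray(X, dtype=float).reshape(-1)
        y = np.asarray(y, dtype=float).reshape(-1)
        if x.shape != y.shape:
            raise ValueError("X and y must have the same length")
        if x.size < 3:
            raise ValueError("Deming regression needs >= 3 pairs")
        self.slope_, self.intercept_ = _deming_closed_form(x, y, self.variance_ratio)
        self.n_ = int(x.size)
        self.ci_slope_ = self.ci_intercept_ = None
        if self.ci and x.size >= 4:
            self.ci_slope_, self.ci_intercept_ = self._jackknife_ci(x, y)
        return self

    def _jackknife_ci(self, x: np.ndarray, y: np.ndarray):
        n = x.size
        stats = []
        for i in range(n):
            mask = np.ones(n, dtype=bool)
            mask[i] = False
            try:
                stats.append(_deming_closed_form(x[mask], y[mask], self.variance_ratio))
            except ValueError:
                return None, None
        stats = np.asarray(stats)  # (n, 2): slope, intercept
        mean = stats.mean(axis=0)
        var = (n - 1) / n * np.sum((stats - mean) ** 2, axis=0)
        se = np.sqrt(var)
        tcrit = scipy.stats.t.ppf(0.975, n - 1)
        est = np.array([self.slope_, self.intercept_])
        lo, hi = est - tcrit * se, est + tcrit * se
        return (float(lo[0]), float(hi[0])), (float(lo[1]), float(hi[1]))

    def predict(self, X):
        check_is_fitted(self, "slope_")
        return self.slope_ * np.asarray(X, dtype=float).reshape(-1) + self.intercept_

    def to_fit(self) -> DemingFit:
        check_is_fitted(self, "slope_")
        return DemingFit(
            slope=self.slope_,
            intercept=self.intercept_,
            variance_ratio=self.variance_ratio,
            n=self.n_,
            ci_slope=self.ci_slope_,
            ci_intercept=self.ci_intercept_,
        )


def deming_fit(data: PairedMeasurements, variance_ratio: float = 1.0) -> DemingFit:
    """Fit a Deming regression to paired measurements (δ fixed, default 1)."""
    return DemingRegressor(variance_ratio=variance_ratio).fit(data.x, data.y).to_fit()


def agreement_report(fits: dict) -> pd.DataFrame:
    """Long-format agreement table over per-(target, method-pair) Deming fits.

    A fit "agrees" when its slope 95% CI contains 1; with no CI available a
    fallback of |slope − 1| ≤ 0.2 is used.  Keys of ``fits`` may be
    (target_id, method_pair) tuples or plain strings.
    """
    if not fits:
        raise ValueError("agreement_report needs at least one fit")
    rows = []
    for key, fit in fits.items():
        target, pair = key if isinstance(key, tuple) else (key, "")
        if fit.ci_slope is not None:
            agrees = fit.ci_slope[0] <= 1.0 <= fit.ci_slope[1]
        else:
            agrees = abs(fit.slope - 1.0) <= 0.2
        rows.append(
            {
                "target_id": target,
                "method_pair": pair,
                "slope": fit.slope,
                "intercept": fit.intercept,
                "ci_slope_low": None if fit.ci_slope is None else fit.ci_slope[0],
                "ci_slope_high": None if fit.ci_slope is None else fit.ci_slope[1],
                "ci_intercept_low": None if fit.ci_intercept is None else fit.ci_intercept[0],
                "ci_intercept_high": None if fit.ci_intercept is None else fit.ci_intercept[1],
                "n": fit.n,
                "agreement": "agrees" if agrees else "discrepant",
            }
        )
    return pd.DataFrame(rows)
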