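"""Internal-standard calibration, merit statistics and glycoside diagnostics.

Quantitation uses the peak-area ratio R = analyte area / internal-standard
area as the response.  Calibration is a weighted linear regression of R on
concentration x (ng/mL) with weights w_i = 1/x_i, which equalises the
relative influence of low and high standards over a wide dynamic range
(here 0.5–10000 ng/mL).  Merit statistics follow the replicate-SD
convention: LOD = 3·SD, LOQ = 10·SD, with SD the sample standard deviation
of back-calculated concentrations from replicate injections of the lowest
quantifiable standard.  The linear range is the widest contiguous run of
calibration levels whose mean back-calculated accuracy is within a
tolerance (default ±20%).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from sklearn.base import BaseEstimator, RegressorMixin
from sklearn.utils.validation import check_is_fitted

from .extract import TargetArea

__all__ = [
    "CalibrationPoint",
    "CalibrationCurve",
    "MeritReport",
    "CalibrationModel",
    "normalize_response",
    "fit_calibration",
    "back_calculate",
    "limits_of_detection",
    "intraday_cv",
    "determine_linear_range",
    "glycone_aglycone_ratio",
    "merit_report",
]


@dataclass(frozen=True)
class CalibrationPoint:
    """One calibration observation: concentration (ng/mL) and response ratio."""

    concentration: float
    response: float
    replicate_id: str = ""

    def __post_init__(self) -> None:
        if self.concentration < 0:
            raise ValueError("concentration must be >= 0")
        if self.response < 0:
            raise ValueError("response must be >= 0")


@dataclass(frozen=True)
class CalibrationCurve:
    """Fitted weighted line R = m·x + b."""

    slope: float
    intercept: float
    weighting: str  # "1/x" | "none"
    r_squared: float
    residual_sd: float
    n_points: int

    def __post_init__(self) -> None:
        if self.n_points < 2:
            raise ValueError("calibration needs >= 2 points")
        if not (np.isfinite(self.slope) and np.isfinite(self.intercept)):
            raise ValueError("non-finite calibration coefficients")


@dataclass(frozen=True)
class MeritReport:
    """Per-target figures of merit on one acquisition method."""

    target_id: str
    method: str  # prm | dda_ms1 | mrm
    sd: float
    lod: float
    loq: float
    linear_range: tuple[float, float]

    def __post_init__(self) -> None:
        if abs(self.lod - 3.0 * self.sd) > 1e-12 * max(1.0, self.sd):
            raise ValueError("LOD must equal 3 x SD")
        if abs(self.loq - 10.0 * self.sd) > 1e-12 * max(1.0, self.sd):
            raise ValueError("LOQ must equal 10 x SD")


class CalibrationModel(BaseEstimator, RegressorMixin):
    """Weighted linear calibration curve as a scikit-learn estimator.

    Parameters
    ----------
    weighting : {"1/x", "none"}
        "1/x" down-weights high standards proportionally to concentration
        (weights w_i = 1/x_i); zero-concentration points are excluded with a
        warning since their weight is undefined.

    Attributes
    ----------
    slope_, intercept_ : float
        Coefficients of R = slope·x + intercept minimising Σ w_i (R_i − m x_i − b)².
    r_squared_ : float
        Weighted coefficient of determination.
    residual_sd_ : float
        Weighted root-mean-square residual (response units, n−2 denominator).
    n_points_ : int
        Number of points used in the fit (after any exclusion).
    """

    def __init__(self, weighting: str = "1/x"):
        self.weighting = weighting

    def fit(self, X, y):
        if self.weighting not in ("1/x", "none"):
            raise ValueError(f"weighting must be '1/x' or 'none', got {self.weighting!r}")
        x = np.asarray(X, dtype=float).reshape(-1)
        y = np.asarray(y, dtype=float).reshape(-1)
        if x.shape != y.shape:
            raise ValueError("X and y must have the same length")
        if self.weighting == "1/x":
            zero = x <= 0
            if zero.any():
                warnings.warn(
                    f"excluding {int(zero.sum())} zero-concentration point(s) "
                    "from 1/x-weighted fit (weight undefined)",
                    stacklevel=2,
                )
                x, y = x[~zero], y[~zero]
        if np.unique(x).size < 2:
            raise ValueError("calibration requires >= 2 distinct concentrations")
        w = 1.0 / x if self.weighting == "1/x" else np.ones_like(x)
        res = sm.WLS(y, sm.add_constant(x), weights=w).fit()
        self.intercept_ = float(res.params[0])
        self.slope_ = float(res.params[1])
        self.r_squared_ = float(res.rsquared)
        dof = x.size - 2
        wres = np.sqrt(w) * (y - self.slope_ * x - self.intercept_)
        self.residual_sd_ = float(np.sqrt(np.sum(wres**2) / dof)) if dof > 0 else float("nan")
        self.n_points_ = int(x.size)
        return self

    def predict(self, X):
        check_is_fitted(self, "slope_")
        x = np.asarray(X, dtype=float).reshape(-1)
        return self.slope_ * x + self.intercept_

    def inverse_predict(self, response):
        """Back-calculate concentration(s) from response(s): x̂ = (R − b)/m."""
        check_is_fitted(self, "slope_")
        if self.slope_ == 0:
            raise ZeroDivisionError("calibration slope is zero; cannot back-calculate")
        r = np.asarray(response, dtype=float)
        return (r - self.intercept_) / self.slope_

    def to_curve(self) -> CalibrationCurve:
        check_is_fitted(self, "slope_")
        return CalibrationCurve(
            slope=self.slope_,
            intercept=self.intercept_,
            weighting=self.weighting,
            r_squared=self.r_squared_,
            residual_sd=self.residual_sd_,
            n_points=self.n_points_,
        )


def normalize_response(analyte: TargetArea, internal_standard: TargetArea) -> float:
    """Peak-area ratio analyte/IS; the IS must have a positive area."""
    if internal_standard.area <= 0:
        raise ValueError(
            f"internal standard area is {internal_standard.area} in sample "
            f"{internal_standard.sample_id!r}; cannot normalize"
        )
    return analyte.area / internal_standard.area


def fit_calibration(points: list[CalibrationPoint], weighting: str = "1/x") -> CalibrationCurve:
    """Fit the weighted calibration line through a list of points."""
    x = [p.concentration for p in points]
    y = [p.response for p in points]
    return CalibrationModel(weighting=weighting).fit(x, y).to_curve()


def back_calculate(curve: CalibrationCurve, response: float) -> float:
    """Concentration from response: x̂ = (R − b)/m.

    Sub-blank responses give negative concentrations; they are returned
    as-is (callers may flag them) rather than clipped.
    """
    if curve.slope == 0:
        raise ZeroDivisionError("calibration slope is zero; cannot back-calculate")
    return (response - curve.intercept) / curve.slope


def limits_of_detection(sd: float) -> tuple[float, float]:
    """(LOD, LOQ) = (3·SD, 10·SD) in ng/mL from a replicate SD in ng/mL."""
    if sd < 0:
        raise ValueError("sd must be >= 0")
    return 3.0 * sd, 10.0 * sd


def intraday_cv(values) -> float:
    """Percent coefficient of variation, sample SD (n−1) over mean."""
    v = np.asarray(values, dtype=float)
    if v.size < 2:
        raise ValueError("CV needs >= 2 values")
    mean = v.mean()
    if mean <= 0:
        raise ValueError(f"CV undefined for non-positive mean ({mean})")
    return 100.0 * v.std(ddof=1) / mean


def determine_linear_range(
    points: list[CalibrationPoint],
    curve: CalibrationCurve,
    accuracy_tol: float = 0.20,
) -> tuple[float, float]:
    """Widest contiguous run of levels with mean back-calculated accuracy
    within ``accuracy_tol`` (fractional, default 20%).

    Returns (lowest, highest) passing level concentration.  Raises if no
    level passes, listing per-level accuracies.
    """
    df = pd.DataFrame(
        {"x": [p.concentration for p in points], "r": [p.response for p in points]}
    )
    levels = sorted(df["x"].unique())
    if len(levels) < 3:
        raise ValueError("linear-range determination needs >= 3 levels")
    accuracy = {}
    for level in levels:
        if level <= 0:
            continue
        resp = df.loc[df["x"] == level, "r"]
        xhat = (resp - curve.intercept) / curve.slope
        accuracy[level] = float(np.abs(xhat / level - 1.0).mean())
    passing = [lvl for lvl in accuracy if accuracy[lvl] <= accuracy_tol]
    if not passing:
        detail = ", ".join(f"{lvl}: {acc:.1%}" for lvl, acc in accuracy.items())
        raise ValueError(f"no calibration level within ±{accuracy_tol:.0%} accuracy ({detail})")
    ordered = sorted(accuracy)
    ok = [accuracy[lvl] <= accuracy_tol for lvl in ordered]
    best_run, cur_start = (0, -1), None
    for i, flag in enumerate(ok + [False]):
        if flag and cur_start is None:
            cur_start = i
        elif not flag and cur_start is not None:
            if i - cur_start > best_run[0]:
                best_run = (i - cur_start, cur_start)
            cur_start = None
    length, start = best_run
    return ordered[start], ordered[start + length - 1]


def glycone_aglycone_ratio(glycone_area: float, aglycone_area: float) -> float:
    """Intact-glycoside to sugar-loss-product signal ratio.

    Diagnoses in-source fragmentation harshness: the ratio falls as the
    source converts more of the intact glycoside into its aglycone.
    """
    if aglycone_area <= 0:
        raise ValueError(f"aglycone area must be > 0, got {aglycone_area}")
    return glycone_area / aglycone_area


def merit_report(
    target_id: str,
    method: str,
    replicate_concentrations,
    points: list[CalibrationPoint],
    curve: CalibrationCurve,
    accuracy_tol: float = 0.20,
) -> MeritReport:
    """Assemble LOD/LOQ (from replicate back-calculated concentrations of the
    lowest quantifiable standard) and the linear range into one report."""
    v = np.asarray(replicate_concentrations, dtype=float)
    if v.size < 2:
        raise ValueError("merit SD needs >= 2 replicate concentrations")
    sd = float(v.std(ddof=1))
    lod, loq = limits_of_detection(sd)
    rng = determine_linear_range(points, curve, accuracy_tol)
    return MeritReport(target_id, method, sd, lod, loq, rng)
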