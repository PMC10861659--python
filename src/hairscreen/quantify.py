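"""Matrix-matched calibration, LOD estimation, and back-calculation.

Quantitation works on internal-standard response ratios. A calibration
curve is an unweighted ordinary-least-squares line of response ratio on
nominal concentration, built from at least six usable levels; the LOD is
the lowest calibrator whose mean response ratio reaches three times the
standard deviation of blank response ratios (an S/N >= 3 rule at the
response level). Concentrations outside the linear range are estimated by
extrapolation and flagged; negative back-calculations clamp to zero with a
censored flag. Curves with r-squared below 0.99 are flagged, not rejected.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import NamedTuple, Optional

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, RegressorMixin

__all__ = [
    "CalibrationCurve",
    "CalibrationModel",
    "BackCalc",
    "fit_calibration",
    "estimate_lod",
    "back_calculate",
    "quantify_study",
]

MIN_LEVELS = 6
R2_FLAG = 0.99


@dataclass(frozen=True)
class CalibrationCurve:
    analyte: str
    matrix: str
    levels: tuple[tuple[float, float], ...]   # (nominal conc, mean response ratio)
    slope: float
    intercept: float
    r_squared: float
    lod: float
    linear_range: tuple[float, float]
    n_levels_used: int
    r2_flagged: bool = False
    lod_flagged: bool = False                 # no level reached S/N >= 3

    @property
    def accepted(self) -> bool:
        return self.slope > 0 and not self.lod_flagged


class BackCalc(NamedTuple):
    conc: float
    extrapolated: bool
    censored: bool


class CalibrationModel(RegressorMixin, BaseEstimator):
    """OLS calibration line as a scikit-learn regressor.

    ``fit(X, y)`` takes nominal concentrations (n_samples, 1) and response
    ratios; fitted attributes are ``slope_``, ``intercept_``,
    ``r_squared_`` and, when blank responses are supplied, ``lod_``.
    ``predict`` maps concentration to expected response ratio and
    ``back_calculate`` inverts a measured ratio.
    """

    def __init__(self, min_levels: int = MIN_LEVELS, r2_flag: float = R2_FLAG,
                 weighting: Optional[str] = None):
        self.min_levels = min_levels
        self.r2_flag = r2_flag
        self.weighting = weighting  # None (default, unweighted) or "1/x2"

    def fit(self, X, y, blank_responses=None):
        X = np.asarray(X, dtype=float).reshape(-1)
        y = np.asarray(y, dtype=float).reshape(-1)
        if X.shape != y.shape:
            raise ValueError("X and y length mismatch")
        if len(np.unique(X)) < self.min_levels:
            raise ValueError(
                f"calibration requires >= {self.min_levels} distinct levels, "
                f"got {len(np.unique(X))}"
            )
        if np.ptp(X) == 0:
            raise ValueError("zero variance in nominal concentrations")
        w = 1.0 / X**2 if self.weighting == "1/x2" else np.ones_like(X)
        sw = w.sum()
        xm, ym = (w * X).sum() / sw, (w * y).sum() / sw
        sxx = (w * (X - xm) ** 2).sum()
        self.slope_ = float((w * (X - xm) * (y - ym)).sum() / sxx)
        self.intercept_ = float(ym - self.slope_ * xm)
        resid = y - (self.slope_ * X + self.intercept_)
        sst = ((y - y.mean()) ** 2).sum()
        self.r_squared_ = float(1.0 - (resid**2).sum() / sst) if sst > 0 else 0.0
        self.n_levels_used_ = int(len(np.unique(X)))
        self.levels_ = tuple(sorted(zip(X.tolist(), y.tolist())))
        if blank_responses is not None:
            self.lod_ = estimate_lod(blank_responses, self.levels_)
        else:
            self.lod_ = float(X.min())
        low = max(float(X.min()), self.lod_) if math.isfinite(self.lod_) else float(X.min())
        self.linear_range_ = (low, float(X.max()))
        return self

    def predict(self, X):
        X = np.asarray(X, dtype=float).reshape(-1)
        return self.slope_ * X + self.intercept_

    def back_calculate(self, response_ratio: float) -> BackCalc:
        if self.slope_ <= 0:
            raise ValueError("curve not accepted: non-positive slope")
        conc = (float(response_ratio) - self.intercept_) / self.slope_
        if conc <= 0:  # nothing measurable: clamp and censor
            return BackCalc(0.0, False, True)
        lo, hi = self.linear_range_
        return BackCalc(conc, not (lo <= conc <= hi), False)


def estimate_lod(blank_responses, levels) -> float:
    """Lowest calibrator whose mean response reaches 3 x SD(blanks).

    ``levels`` is an iterable of (nominal conc, mean response ratio).
    Returns +inf when no level qualifies (flagged not-detectable).
    """
    blanks = np.asarray(blank_responses, dtype=float)
    if blanks.size == 0:
        raise ValueError("blank responses required")
    if blanks.size < 3:
        raise ValueError("need >= 3 blank replicates")
    threshold = 3.0 * float(np.std(blanks, ddof=1))
    for conc, resp in sorted(levels):
        if resp >= threshold:
            return float(conc)
    return math.inf


def fit_calibration(
    samples: pd.DataFrame | list[tuple[float, float]],
    blank_responses=None,
    analyte: str = "",
    matrix: str = "plasma",
    weighting: Optional[str] = None,
) -> CalibrationCurve:
    """Fit one calibration curve; thin wrapper over CalibrationModel.

    ``samples`` is either a DataFrame with nominal_conc / response_ratio
    columns or a list of (nominal conc, response ratio) pairs. Replicate
    levels are averaged before the LOD rule; the OLS uses all points.
    """
    if isinstance(samples, pd.DataFrame):
        pairs = list(zip(samples["nominal_conc"], samples["response_ratio"]))
    else:
        pairs = list(samples)
    x = np.array([p[0] for p in pairs], dtype=float)
    y = np.array([p[1] for p in pairs], dtype=float)
    model = CalibrationModel(weighting=weighting).fit(x, y, blank_responses=blank_responses)
    level_means = tuple(
        (float(c), float(y[x == c].mean())) for c in np.unique(x)
    )
    return CalibrationCurve(
        analyte=analyte,
        matrix=matrix,
        levels=level_means,
        slope=model.slope_,
        intercept=model.intercept_,
        r_squared=model.r_squared_,
        lod=model.lod_,
        linear_range=model.linear_range_,
        n_levels_used=model.n_levels_used_,
        r2_flagged=model.r_squared_ < R2_FLAG,
        lod_flagged=not math.isfinite(model.lod_),
    )


def back_calculate(curve: CalibrationCurve, response_ratio: float) -> BackCalc:
    """Invert a response ratio through a fitted curve."""
    if curve.slope <= 0:
        raise ValueError("curve not accepted: non-positive slope")
    conc = (float(response_ratio) - curve.intercept) / curve.slope
    if conc <= 0:  # nothing measurable: clamp and censor
        return BackCalc(0.0, False, True)
    lo, hi = curve.linear_range
    return BackCalc(conc, not (lo <= conc <= hi), False)


def quantify_study(responses: pd.DataFrame, weighting: Optional[str] = None):
    """Quantify a full response table.

    Fits one curve per substance x matrix from its calibrator and blank
    rows, then back-calculates every sample row; values below the curve
    LOD are censored to 0. Returns (concentration frame in the standard
    schema, dict of curves keyed by (substance, matrix)).
    """
    required = {"substance", "matrix", "role", "nominal_conc", "response_ratio",
                "animal_id", "group", "day", "time_h"}
    missing = required - set(responses.columns)
    if missing:
        raise ValueError(f"missing required column(s): {', '.join(sorted(missing))}")

    curves: dict[tuple[str, str], CalibrationCurve] = {}
    rows = []
    for (sub, mat), part in responses.groupby(["substance", "matrix"], sort=True):
        cal = part[part["role"] == "calibrator"]
        blanks = part.loc[part["role"] == "blank", "response_ratio"].to_numpy()
        curve = fit_calibration(
            cal, blank_responses=blanks if blanks.size else None,
            analyte=str(sub), matrix=str(mat), weighting=weighting,
        )
        curves[(str(sub), str(mat))] = curve
        lod = curve.lod
        for r in part[part["role"] == "sample"].itertuples():
            conc, _extrap, censored = back_calculate(curve, r.response_ratio)
            if censored or conc < lod:
                value, cens = 0.0, True
            else:
                value, cens = conc, False
            rows.append(
                (str(sub), str(mat), r.animal_id, r.group, int(r.day),
                 float(r.time_h), value, cens)
            )
    frame = pd.DataFrame(
        rows,
        columns=["substance", "matrix", "animal_id", "group", "day", "time_h",
                 "value", "censored"],
    )
    return frame, curves
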