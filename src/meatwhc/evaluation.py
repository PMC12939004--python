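"""Model-quality metrics and wet-lab water-holding-capacity formulas.

Calibration/validation fit is summarized by the coefficient of
determination and root mean square error, each computed set-locally:

    R^2   = 1 - sum (y_act - y_pre)^2 / sum (y_act - ybar)^2
    RMSE  = sqrt( sum (y_act - y_pre)^2 / N )

with ybar the mean of the actual values in the evaluated set.  Residuals
follow the convention Res = y_act - y_pre; validation residuals are
standardized by the calibration-residual standard deviation, and a model
is flagged reliable when every standardized validation residual has
magnitude strictly below 1.

Predictive quality bands (on the validation R^2): high for R^2 > 0.90,
good for 0.81 <= R^2 <= 0.90, moderate for 0.66 <= R^2 < 0.81 (the
nominally uncovered sliver (0.80, 0.81) is assigned to moderate for
continuity), poor below 0.66.

The gravimetric formulas express each water loss as a percentage of the
initial mass; moisture content uses bottle / bottle+sample /
bottle+dried-sample masses.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "Metrics", "r_squared", "rmse", "residuals", "standardize", "quality_band",
    "compute_metrics", "moisture_content", "drip_loss", "cooking_loss",
    "pressing_loss", "relative_reduction", "msep",
]


def r_squared(y_act, y_pre) -> float:
    """Coefficient of determination, set-local mean in the denominator."""
    y_act = np.asarray(y_act, dtype=np.float64).ravel()
    y_pre = np.asarray(y_pre, dtype=np.float64).ravel()
    if y_act.shape != y_pre.shape:
        raise ValueError("length mismatch")
    if y_act.size < 2:
        raise ValueError("need at least 2 observations")
    ss_tot = float(np.sum((y_act - y_act.mean()) ** 2))
    if ss_tot == 0.0:
        raise ValueError("y_act is constant; R^2 undefined")
    ss_res = float(np.sum((y_act - y_pre) ** 2))
    return 1.0 - ss_res / ss_tot


def rmse(y_act, y_pre) -> float:
    """Root mean square error in response units."""
    y_act = np.asarray(y_act, dtype=np.float64).ravel()
    y_pre = np.asarray(y_pre, dtype=np.float64).ravel()
    if y_act.shape != y_pre.shape:
        raise ValueError("length mismatch")
    if y_act.size == 0:
        raise ValueError("empty vectors")
    return float(np.sqrt(np.mean((y_act - y_pre) ** 2)))


def msep(y_act, y_pre) -> float:
    """Mean squared error of prediction (RMSE squared)."""
    return rmse(y_act, y_pre) ** 2


def residuals(y_act, y_pre) -> np.ndarray:
    """Res = y_act - y_pre, element-wise."""
    y_act = np.asarray(y_act, dtype=np.float64).ravel()
    y_pre = np.asarray(y_pre, dtype=np.float64).ravel()
    if y_act.shape != y_pre.shape:
        raise ValueError("length mismatch")
    return y_act - y_pre


def standardize(res: np.ndarray, calibration_sd: float) -> tuple[np.ndarray, bool]:
    """Divide residuals by the calibration-residual standard deviation.

    Returns the standardized residuals and a reliability flag that is
    true iff every |standardized residual| is strictly below 1.
    """
    if calibration_sd <= 0:
        raise ValueError("calibration_sd must be positive")
    std = np.asarray(res, dtype=np.float64) / calibration_sd
    return std, bool(np.all(np.abs(std) < 1.0))


def quality_band(r2: float) -> str:
    """Map a validation R^2 to its predictive-quality band."""
    if r2 > 1.0:
        raise ValueError("R^2 cannot exceed 1")
    if r2 > 0.90:
        return "high"
    if r2 >= 0.81:
        return "good"
    if r2 >= 0.66:
        return "moderate"
    return "poor"


@dataclass(frozen=True)
class Metrics:
    """Calibration/validation summary of one regression model."""

    r2_cal: float
    rmsec: float
    r2_val: float
    rmsep: float
    residuals_cal: np.ndarray
    residuals_val: np.ndarray
    std_residuals_val: np.ndarray
    reliable: bool
    quality_band: str

    def summary(self) -> dict:
        return {
            "r2_cal": self.r2_cal, "rmsec": self.rmsec,
            "r2_val": self.r2_val, "rmsep": self.rmsep,
            "reliable": self.reliable, "quality_band": self.quality_band,
        }


def compute_metrics(y_cal_act, y_cal_pre, y_val_act, y_val_pre) -> Metrics:
    """Full metric set for a fitted model on a fixed holdout split."""
    res_c = residuals(y_cal_act, y_cal_pre)
    res_v = residuals(y_val_act, y_val_pre)
    cal_sd = float(np.std(res_c, ddof=1))
    if cal_sd > 0:
        std_v, reliable = standardize(res_v, cal_sd)
    else:                              # perfect calibration fit
        std_v = np.where(res_v == 0.0, 0.0, np.inf)
        reliable = bool(np.all(res_v == 0.0))
    r2v = r_squared(y_val_act, y_val_pre)
    return Metrics(
        r2_cal=r_squared(y_cal_act, y_cal_pre),
        rmsec=rmse(y_cal_act, y_cal_pre),
        r2_val=r2v,
        rmsep=rmse(y_val_act, y_val_pre),
        residuals_cal=res_c,
        residuals_val=res_v,
        std_residuals_val=std_v,
        reliable=reliable,
        quality_band=quality_band(r2v),
    )


def _check_positive(**masses: float) -> None:
    for name, v in masses.items():
        if v <= 0:
            raise ValueError(f"{name} must be positive, got {v}")


def moisture_content(m1: float, m2: float, m3: float) -> float:
    """Moisture %: (m3 - m1) / (m2 - m1) * 100.

    m1 = weighing bottle, m2 = bottle + sample, m3 = bottle + dried sample.
    """
    _check_positive(m1=m1, m2=m2, m3=m3)
    if m2 <= m1:
        raise ValueError("m2 must exceed m1 (bottle plus sample)")
    return (m3 - m1) / (m2 - m1) * 100.0


def _mass_loss(m1: float, m2: float) -> float:
    _check_positive(m1=m1, m2=m2)
    return (m1 - m2) / m1 * 100.0


def drip_loss(m1: float, m2: float) -> float:
    """Drip loss %: mass before vs after 24 h refrigerated suspension."""
    return _mass_loss(m1, m2)


def cooking_loss(m1: float, m2: float) -> float:
    """Cooking loss %: mass before vs after water-bath cooking."""
    return _mass_loss(m1, m2)


def pressing_loss(m1: float, m2: float) -> float:
    """Pressing loss %: mass before vs after constant-load pressing."""
    return _mass_loss(m1, m2)


def relative_reduction(v0: float, v1: float) -> float:
    """Percentage drop from a baseline value: 100 * (v0 - v1) / v0."""
    if v0 <= 0:
        raise ValueError("baseline must be positive")
    return 100.0 * (v0 - v1) / v0
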