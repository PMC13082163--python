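"""Threshold linear model of laser effects: R_laser = max(0, a*R_control + b).

The TLM maps the control tuning curve onto the laser curve with a gain ``a``
and an offset ``b``, rectifying negative predictions at zero.  Rectification
is the model's only route to tuning sharpening (the "iceberg effect": the
trough of the tuning curve is clipped to zero, narrowing the apparent peak).
Fits under PV inactivation omit the rectification, since laser responses
there only move upward.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import least_squares

from .tuning import TuningCurve

__all__ = ["TLMFit", "fit_tlm", "simulate_tlm"]


@dataclass
class TLMFit:
    """Slope, offset and goodness of the rectified-linear control-to-laser map."""

    a: float
    b: float
    r_squared: float
    rectified: bool = True

    def predict(self, r_control: np.ndarray) -> np.ndarray:
        pred = self.a * np.asarray(r_control, dtype=float) + self.b
        return np.maximum(pred, 0.0) if self.rectified else pred


def fit_tlm(
    r_control: np.ndarray, r_laser: np.ndarray, rectify: bool = True
) -> TLMFit:
    """Least-squares fit of the TLM, initialised from the unrectified OLS line.

    ``rectify=False`` fits a plain linear map (used for PV inactivation).
    Raises on fewer than 4 points or a constant control curve (slope
    unidentifiable).
    """
    x = np.asarray(r_control, dtype=float)
    y = np.asarray(r_laser, dtype=float)
    if x.size != y.size or x.size < 4:
        raise ValueError("need >= 4 paired rate samples")
    if np.ptp(x) < 1e-12:
        raise ValueError("constant control curve: slope unidentifiable")

    a0, b0 = np.polyfit(x, y, 1)
    if rectify:
        def resid(p: np.ndarray) -> np.ndarray:
            return np.maximum(p[0] * x + p[1], 0.0) - y

        sol = least_squares(resid, np.array([a0, b0]), method="trf")
        a, b = sol.x
        pred = np.maximum(a * x + b, 0.0)
    else:
        a, b = a0, b0
        pred = a * x + b

    ss_res = float(np.sum((y - pred) ** 2))
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 if ss_tot <= 0 and ss_res < 1e-12 else max(0.0, 1.0 - ss_res / max(ss_tot, 1e-30))
    return TLMFit(a=float(a), b=float(b), r_squared=min(1.0, r2), rectified=rectify)


def simulate_tlm(control_curve: TuningCurve, fit: TLMFit) -> TuningCurve:
    """Apply the fitted TLM elementwise to a control curve."""
    return TuningCurve(
        directions=control_curve.directions,
        mean_rate=fit.predict(control_curve.mean_rate),
        role="laser",
        unit_id=control_curve.unit_id,
        intensity_id=control_curve.intensity_id,
    )
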