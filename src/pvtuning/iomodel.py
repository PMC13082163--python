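"""Escape-rate input/output model of the membrane-potential-to-rate transform.

The model is ``rate = exp(beta * (u - theta))``: a neuron with membrane
potential ``u`` fires stochastically even below its threshold ``theta``,
with ``beta`` setting how sharply the firing probability rises around
threshold (high beta = low input noise, near-deterministic threshold).

Because the transform is exponential, its absolute parameters are not
identifiable from a single tuning curve — changing (beta, theta) merely
scales/shifts the inferred membrane curve.  The analysis therefore adopts
the baseline convention (beta = 1, theta = 0) to invert the higher-firing
rate tuning curve into a membrane-potential tuning curve, and fits the
(beta, theta) that best transform that membrane curve into the
lower-firing-rate curve.  A threshold increase alone reproduces a pure
divisive/multiplicative rate change (exactly multiplicative, by the algebra
of the exponential); a beta increase combined with a threshold drop — with
the membrane drive scaled by the granular-layer gain ``alpha`` — reproduces
the non-linear sharpening effect.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import least_squares

from .tuning import TuningCurve

__all__ = [
    "IOParams",
    "MembraneCurve",
    "io_function",
    "inverse_io",
    "membrane_curve",
    "laser_membrane_curve",
    "fit_io",
    "simulate_io_laser",
]

#: normalized rates are floored here before logarithms (inverse I/O domain)
NORM_RATE_FLOOR = 1e-3


@dataclass
class IOParams:
    """Escape-rate parameters plus the membrane gain of the NL pathway."""

    beta: float = 1.0
    theta: float = 0.0
    alpha: float = 1.0
    u_rest: float = 0.0

    def __post_init__(self) -> None:
        if self.beta <= 0 or self.alpha <= 0:
            raise ValueError("beta and alpha must be positive")


@dataclass
class MembraneCurve:
    """Membrane-potential tuning curve on a direction grid.

    ``peak_rate`` stores the rate (Hz) the curve was normalised by, so
    simulated rates can be mapped back to Hz.
    """

    grid: np.ndarray
    u: np.ndarray
    condition: str = "control"  # control (TMC) | laser (TML)
    peak_rate: float = 1.0

    def __post_init__(self) -> None:
        self.grid = np.asarray(self.grid, dtype=float)
        self.u = np.asarray(self.u, dtype=float)
        if not np.all(np.isfinite(self.u)):
            raise ValueError("membrane curve must be finite everywhere")


def io_function(u: np.ndarray | float, params: IOParams) -> np.ndarray | float:
    """Forward escape-rate transform exp(beta * (u - theta))."""
    return np.exp(params.beta * (np.asarray(u, dtype=float) - params.theta))


def inverse_io(rate: np.ndarray | float, params: IOParams) -> np.ndarray | float:
    """Inverse transform u = theta + log(rate)/beta; requires rate > 0."""
    rate = np.asarray(rate, dtype=float)
    if np.any(rate <= 0):
        raise ValueError("inverse I/O undefined for non-positive rates")
    return params.theta + np.log(rate) / params.beta


def membrane_curve(t_high: TuningCurve) -> MembraneCurve:
    """Invert the higher-rate tuning curve into a membrane-potential curve.

    Rates are normalised to peak 1 and floored before inversion under the
    baseline convention (beta = 1, theta = 0), so the peak maps to u = 0.
    """
    rates = np.asarray(t_high.mean_rate, dtype=float)
    peak = float(rates.max())
    if peak <= 0:
        raise ValueError("cannot invert an all-zero curve")
    norm = np.maximum(rates / peak, NORM_RATE_FLOOR)
    u = np.asarray(inverse_io(norm, IOParams()))
    return MembraneCurve(grid=t_high.directions, u=u, condition="control", peak_rate=peak)


def laser_membrane_curve(
    tmc: MembraneCurve, spont_rate: float, alpha: float
) -> MembraneCurve:
    """Gain-scale membrane deviations from rest: TML = alpha*(TMC - u_rest) + u_rest.

    The resting potential is derived from the spontaneous rate (normalised by
    the same peak as the tuning curve) through the inverse I/O function; it
    is the fixed point of the gain scaling.
    """
    if alpha <= 0:
        raise ValueError("alpha must be positive")
    spont_norm = max(spont_rate / tmc.peak_rate, NORM_RATE_FLOOR)
    u_rest = float(inverse_io(spont_norm, IOParams()))
    return MembraneCurve(
        grid=tmc.grid,
        u=alpha * (tmc.u - u_rest) + u_rest,
        condition="laser",
        peak_rate=tmc.peak_rate,
    )


def fit_io(tm: MembraneCurve, t_low: TuningCurve) -> tuple[IOParams, float]:
    """Fit (beta, theta) transforming the membrane curve into the low-rate curve.

    The low-rate curve is normalised by the same peak as the membrane curve's
    source.  Least squares is run on rates (not log rates) with multi-start
    over beta in {0.5, 1, 2, 4} plus a log-linear regression start; beta is
    constrained positive.  Returns the best-fitting parameters and R^2.
    """
    if tm.grid.shape != t_low.directions.shape or not np.allclose(
        tm.grid, t_low.directions
    ):
        raise ValueError("membrane curve and low-rate curve must share a grid")
    if np.ptp(tm.u) < 1e-12:
        raise ValueError("constant membrane curve: parameters unidentifiable")
    y = np.maximum(np.asarray(t_low.mean_rate, dtype=float) / tm.peak_rate, NORM_RATE_FLOOR)
    u = tm.u

    # exact in the noiseless case: log y is linear in u
    slope, intercept = np.polyfit(u, np.log(y), 1)
    starts = [(max(slope, 1e-3), -intercept / max(slope, 1e-3))]
    starts += [(b, 0.0) for b in (0.5, 1.0, 2.0, 4.0)]

    def resid(p: np.ndarray) -> np.ndarray:
        return np.exp(p[0] * (u - p[1])) - y

    best = None
    for b0, th0 in starts:
        sol = least_squares(
            resid,
            np.array([b0, th0]),
            bounds=(np.array([1e-3, -50.0]), np.array([200.0, 50.0])),
            method="trf",
        )
        if best is None or sol.cost < best.cost:
            best = sol
    beta, theta = best.x
    pred = np.exp(beta * (u - theta))
    ss_res = float(np.sum((y - pred) ** 2))
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 if ss_tot <= 0 and ss_res < 1e-12 else max(0.0, 1.0 - ss_res / max(ss_tot, 1e-30))
    return IOParams(beta=float(beta), theta=float(theta)), min(1.0, r2)


def simulate_io_laser(
    t_high: TuningCurve,
    params: IOParams,
    pathway: str = "DM",
    spont_rate: float | None = None,
) -> TuningCurve:
    """Simulate the low-rate curve from the high-rate curve and fitted params.

    The DM pathway applies the escape-rate transform to the unchanged
    membrane curve (the granular scenario: the manipulation shifts only the
    threshold, leaving the thalamically driven membrane tuning intact); the
    NL pathway first gain-scales the membrane curve by ``params.alpha``
    around the resting potential (requires ``spont_rate``).  Output rates are
    rescaled back to Hz by the stored peak.
    """
    if pathway not in ("DM", "NL"):
        raise ValueError("pathway must be DM or NL")
    tm = membrane_curve(t_high)
    if pathway == "NL":
        if spont_rate is None:
            raise ValueError("NL pathway requires the unit's spontaneous rate")
        tm = laser_membrane_curve(tm, spont_rate, params.alpha)
    rates = tm.peak_rate * np.asarray(io_function(tm.u, params))
    return TuningCurve(
        directions=tm.grid,
        mean_rate=rates,
        role="lowFr",
        unit_id=t_high.unit_id,
        intensity_id=t_high.intensity_id,
    )
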