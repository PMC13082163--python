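"""Orientation tuning-curve fitting and tuning metrics.

The tuning model is a two-harmonic von Mises rate function

    R(theta) = exp(a0 + kappa*(cos(2*(theta - phi)) - 1) + v*(cos(theta - phi) - 1))

with ``theta`` the drift direction in degrees, ``phi`` the central
orientation, ``kappa`` the weight of the second harmonic (orientation
tuning), ``v`` the weight of the first harmonic (direction bias) and
``a0`` a log-baseline.  Because the first harmonic breaks the strict
180-degree symmetry, the preferred and non-preferred orientations are
defined as the global maximum and minimum of the fitted curve rather
than at a fixed angular distance.

Metrics computed from the fit (or from raw trial-mean rates where
noted): preferred/non-preferred orientation, OSI, circular variance,
half-bandwidth and fractional firing-rate change.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import brentq, least_squares, minimize_scalar

__all__ = [
    "TuningCurve",
    "VonMisesFit",
    "TuningMetrics",
    "FlatTuningError",
    "NoFitError",
    "von_mises_rate",
    "fit_von_mises",
    "preferred_orientations",
    "osi",
    "circular_variance",
    "half_bandwidth",
    "delta_fr",
    "compute_metrics",
    "grid_metrics",
]

#: rates below this are floored before taking logarithms inside the fit
RATE_FLOOR = 1e-9

#: kappa and v below this are treated as a flat (untuned) fit
FLAT_TOL = 1e-6


class FlatTuningError(ValueError):
    """Raised when an orientation metric is undefined for a flat curve."""


class NoFitError(RuntimeError):
    """Raised when the von Mises fit cannot be performed (e.g. all-zero curve)."""


@dataclass
class TuningCurve:
    """Direction grid plus trial-mean firing rates for one unit/condition.

    ``role`` records which side of the analysis the curve sits on:
    ``control``/``laser`` name the experimental condition, ``highFr``/
    ``lowFr`` name the manipulation-independent convention in which the
    lower-firing-rate curve is the laser curve under PV activation but
    the control curve under PV inactivation.
    """

    directions: np.ndarray
    mean_rate: np.ndarray
    sem_rate: np.ndarray | None = None
    role: str = "control"
    unit_id: str = ""
    intensity_id: str = ""

    def __post_init__(self) -> None:
        self.directions = np.asarray(self.directions, dtype=float)
        self.mean_rate = np.asarray(self.mean_rate, dtype=float)
        if self.sem_rate is not None:
            self.sem_rate = np.asarray(self.sem_rate, dtype=float)
            if self.sem_rate.shape != self.directions.shape:
                raise ValueError("sem_rate length must match directions")
        if self.directions.shape != self.mean_rate.shape:
            raise ValueError("directions and mean_rate must have equal length")
        if np.any(self.mean_rate < 0):
            raise ValueError("mean_rate must be non-negative")
        if np.any(np.diff(self.directions) <= 0):
            raise ValueError("directions must be strictly increasing")
        if np.any((self.directions < 0) | (self.directions >= 360)):
            raise ValueError("directions must lie in [0, 360)")


def von_mises_rate(
    theta_deg: np.ndarray | float,
    phi: float,
    kappa: float,
    v: float,
    a0: float,
) -> np.ndarray | float:
    """Evaluate the two-harmonic von Mises rate model (Hz)."""
    d = np.deg2rad(np.asarray(theta_deg, dtype=float) - phi)
    out = np.exp(a0 + kappa * (np.cos(2.0 * d) - 1.0) + v * (np.cos(d) - 1.0))
    return out if out.ndim else float(out)


@dataclass
class VonMisesFit:
    """Fitted parameters of the two-harmonic von Mises tuning function."""

    phi: float
    kappa: float
    v: float
    a0: float
    r_squared: float
    converged: bool = True

    def evaluate(self, theta_deg: np.ndarray | float) -> np.ndarray | float:
        return von_mises_rate(theta_deg, self.phi, self.kappa, self.v, self.a0)

    @property
    def is_flat(self) -> bool:
        return self.kappa < FLAT_TOL and self.v < FLAT_TOL


@dataclass
class TuningMetrics:
    """Tuning metrics extracted from a fitted curve (rates in Hz, angles in deg)."""

    theta_P: float
    theta_NP: float
    R_P: float
    R_NP: float
    osi: float
    cv: float
    hbw: float
    fr_mean: float
    r_squared: float = field(default=np.nan)


def _fit_once(directions: np.ndarray, rates: np.ndarray, phi0: float) -> least_squares:
    peak = max(float(rates.max()), RATE_FLOOR)
    x0 = np.array([phi0, 1.0, 0.1, np.log(peak)])
    lo = np.array([phi0 - 180.0, 0.0, 0.0, -30.0])
    hi = np.array([phi0 + 180.0, 50.0, 20.0, 30.0])

    def resid(p: np.ndarray) -> np.ndarray:
        return von_mises_rate(directions, *p) - rates

    return least_squares(resid, x0, bounds=(lo, hi), method="trf")


def fit_von_mises(curve: TuningCurve) -> VonMisesFit:
    """Fit the von Mises model to trial-mean rates by nonlinear least squares.

    Multi-start over the central orientation: the fit is initialised at the
    grid argmax and at its antipode (the model is nearly symmetric under a
    180-degree shift of ``phi`` when ``v`` is small, so both basins are
    explored) and the best solution by residual norm is kept.

    Raises
    ------
    NoFitError
        If the curve has fewer than 8 distinct directions or is all zero.
    """
    dirs = curve.directions
    rates = curve.mean_rate
    if np.unique(dirs).size < 8:
        raise NoFitError("need at least 8 distinct directions to fit")
    if not np.any(rates > 0):
        raise NoFitError("all-zero tuning curve cannot be fitted")

    phi_hat = float(dirs[int(np.argmax(rates))])
    best = None
    for phi0 in (phi_hat, (phi_hat + 180.0) % 360.0):
        sol = _fit_once(dirs, rates, phi0)
        if best is None or sol.cost < best.cost:
            best = sol

    phi, kappa, v, a0 = best.x
    phi = float(phi % 360.0)
    pred = von_mises_rate(dirs, phi, kappa, v, a0)
    ss_res = float(np.sum((rates - pred) ** 2))
    ss_tot = float(np.sum((rates - rates.mean()) ** 2))
    if ss_tot <= 0.0:
        r2 = 1.0 if ss_res < 1e-12 else 0.0
    else:
        r2 = max(0.0, min(1.0, 1.0 - ss_res / ss_tot))
    return VonMisesFit(
        phi=phi,
        kappa=float(kappa),
        v=float(v),
        a0=float(a0),
        r_squared=r2,
        converged=bool(best.success),
    )


def _refine(fun, x0: float, half_window: float = 0.6) -> float:
    res = minimize_scalar(fun, bounds=(x0 - half_window, x0 + half_window), method="bounded")
    return float(res.x)


def preferred_orientations(fit: VonMisesFit) -> tuple[float, float, float, float]:
    """Global argmax/argmin of the fitted curve.

    Scans a 0.5-degree grid over [0, 360) and refines each extremum by
    bounded scalar minimisation.  Returns ``(theta_P, theta_NP, R_P, R_NP)``.

    Raises
    ------
    FlatTuningError
        If the fit is flat (kappa = v = 0), where the orientation of the
        extremum is undefined.
    """
    if fit.is_flat:
        raise FlatTuningError("preferred orientation undefined for a flat fit")
    grid = np.arange(0.0, 360.0, 0.5)
    vals = fit.evaluate(grid)
    theta_p = _refine(lambda t: -fit.evaluate(t), float(grid[int(np.argmax(vals))]))
    theta_np = _refine(fit.evaluate, float(grid[int(np.argmin(vals))]))
    theta_p %= 360.0
    theta_np %= 360.0
    return theta_p, theta_np, float(fit.evaluate(theta_p)), float(fit.evaluate(theta_np))


def osi(r_p: float, r_np: float) -> float:
    """Orientation selectivity index (R_P - R_NP) / (R_P + R_NP) in [0, 1]."""
    if r_p <= 0 and r_np <= 0:
        raise FlatTuningError("OSI undefined when both responses are zero")
    if r_np > r_p:
        raise ValueError("R_P must be >= R_NP")
    return (r_p - r_np) / (r_p + r_np)


def circular_variance(directions: np.ndarray, rates: np.ndarray) -> float:
    """Circular variance of responses on the doubled-orientation circle.

    Each sampled direction is folded to orientation (mod 180 deg), placed on
    the complex plane at angle 2*theta and weighted by its response; CV is one
    minus the normalised resultant length.  1 for responses uniform over
    orientation, 0 for a response concentrated at a single orientation.
    """
    directions = np.asarray(directions, dtype=float)
    rates = np.asarray(rates, dtype=float)
    if np.any(rates < 0):
        raise ValueError("rates must be non-negative")
    total = rates.sum()
    if total <= 0:
        raise FlatTuningError("circular variance undefined for all-zero rates")
    ori = np.deg2rad(directions % 180.0)
    resultant = np.abs(np.sum(rates * np.exp(2j * ori)))
    return float(1.0 - resultant / total)


def half_bandwidth(fit: VonMisesFit) -> float:
    """Half-bandwidth of the fitted peak, in degrees.

    The reference level is the midpoint between the fitted maximum and
    minimum, R_NP + (R_P - R_NP)/2; the two crossings of that level on
    either side of the preferred orientation are located by bisection and
    the HBW is half their angular distance.
    """
    theta_p, _, r_p, r_np = preferred_orientations(fit)
    level = r_np + 0.5 * (r_p - r_np)

    def f(theta: float) -> float:
        return float(fit.evaluate(theta)) - level

    crossings = []
    for sign in (+1.0, -1.0):
        lo = theta_p
        step = 0.5
        x = lo
        found = None
        # march away from the peak until the curve falls below the level
        while abs(x - theta_p) < 180.0:
            x_next = x + sign * step
            if f(x_next) <= 0.0:
                found = (x, x_next) if sign > 0 else (x_next, x)
                break
            x = x_next
        if found is None:
            raise FlatTuningError("half-maximum level never crossed (near-flat fit)")
        crossings.append(brentq(f, found[0], found[1], xtol=1e-10))
    right, left = crossings
    return float((right - left) / 2.0)


def delta_fr(fr_laser: float, fr_control: float) -> float:
    """Fractional laser-induced firing-rate change (Fr_laser - Fr_control)/Fr_control."""
    if fr_control <= 0:
        raise ValueError("delta_fr undefined for non-positive control rate")
    return (fr_laser - fr_control) / fr_control


def grid_metrics(directions: np.ndarray, rates: np.ndarray) -> TuningMetrics:
    """Tuning metrics computed directly on a densely sampled periodic curve.

    Used for curves that are not in the von Mises family (e.g. rectified
    threshold-linear simulations).  The directions must be a uniform grid
    over [0, 360); half-bandwidth crossings are located by marching outward
    from the peak with linear interpolation between samples.
    """
    directions = np.asarray(directions, dtype=float)
    rates = np.asarray(rates, dtype=float)
    n = directions.size
    step = 360.0 / n
    i_p = int(np.argmax(rates))
    i_np = int(np.argmin(rates))
    r_p, r_np = float(rates[i_p]), float(rates[i_np])
    if r_p - r_np < FLAT_TOL * max(r_p, 1.0):
        raise FlatTuningError("metrics undefined for a flat sampled curve")
    level = r_np + 0.5 * (r_p - r_np)
    half_widths = []
    for sign in (+1, -1):
        prev = r_p
        width = None
        for k in range(1, n // 2 + 1):
            cur = float(rates[(i_p + sign * k) % n])
            if cur <= level:
                frac = (prev - level) / (prev - cur)
                width = (k - 1 + frac) * step
                break
            prev = cur
        if width is None:
            raise FlatTuningError("half-maximum level never crossed")
        half_widths.append(width)
    hbw = 0.5 * (half_widths[0] + half_widths[1])
    return TuningMetrics(
        theta_P=float(directions[i_p]),
        theta_NP=float(directions[i_np]),
        R_P=r_p,
        R_NP=r_np,
        osi=osi(r_p, r_np),
        cv=circular_variance(directions, rates),
        hbw=hbw,
        fr_mean=float(rates.mean()),
    )


def compute_metrics(fit: VonMisesFit, curve: TuningCurve | None = None) -> TuningMetrics:
    """Bundle the tuning metrics of a fitted curve.

    OSI, CV and HBW are computed on the fitted curve (CV on a dense grid of
    the fit); ``fr_mean`` is the mean of the raw trial-mean rates when a
    curve is supplied, else the mean of the fitted curve over the grid.
    """
    theta_p, theta_np, r_p, r_np = preferred_orientations(fit)
    grid = np.arange(0.0, 360.0, 0.5)
    fitted = fit.evaluate(grid)
    cv = circular_variance(grid, fitted)
    hbw = half_bandwidth(fit)
    if curve is not None:
        fr_mean = float(curve.mean_rate.mean())
    else:
        fr_mean = float(np.mean(fitted))
    return TuningMetrics(
        theta_P=theta_p,
        theta_NP=theta_np,
        R_P=r_p,
        R_NP=r_np,
        osi=osi(r_p, r_np),
        cv=cv,
        hbw=hbw,
        fr_mean=fr_mean,
        r_squared=fit.r_squared,
    )
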