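"""Unit screening and divisive/multiplicative vs non-linear effect classification.

Every unit is first screened: non-orientation-selective units (raw circular
variance > 0.96) and opsin-tagged PV+ units (firing rate moving with the
manipulation instead of against it) are excluded.  For the remaining units
the difference (dT) and ratio (RT) between the lower- and higher-firing-rate
fitted tuning curves are analysed at the preferred orientation: an upward dT
peak (negative second derivative), or a flat dT (positive second and fourth
derivatives), marks a non-linear (NL) effect; a downward dT peak is tested
with the multiplicative ratio MR — the difference of non-preferred/preferred
rate ratios between conditions — and |MR| < 0.02 marks a pure
divisive/multiplicative (D/M) gain change.  Per-intensity labels are then
consolidated into a unit label (DM, NL, MIX, or unclassified).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .tuning import TuningCurve, VonMisesFit, preferred_orientations

__all__ = [
    "EffectCurves",
    "MR_THRESHOLD",
    "RT_RATE_FLOOR_HZ",
    "screen_unit",
    "effect_curves",
    "multiplicative_ratio",
    "classify_intensity",
    "consolidate_unit",
]

#: |MR| below this marks a pure divisive/multiplicative gain change
MR_THRESHOLD = 0.02

#: grid points where the high-rate curve is below this are excluded from RT
RT_RATE_FLOOR_HZ = 0.5

#: dT curves whose largest excursion is below this are treated as flat
FLAT_DT_TOL_HZ = 1e-6

#: CV above this marks a unit as non-orientation-selective
CV_SCREEN = 0.96


@dataclass
class EffectCurves:
    """dT and RT curves of one unit/intensity with their flatness statistics.

    ``delta_t`` = T_lowFr - T_highFr and ``ratio_t`` = T_lowFr / T_highFr on a
    common dense grid; the coefficient of variation (SD/|mean|) of each curve
    quantifies flatness (CoV(RT) = 0 for a pure gain change, CoV(dT) = 0 for a
    pure additive/subtractive shift).  ``mr`` is the multiplicative ratio.
    """

    grid: np.ndarray
    delta_t: np.ndarray
    ratio_t: np.ndarray  # NaN where T_highFr is below the rate floor
    cov_delta_t: float
    cov_ratio_t: float
    mr: float


def _cov(x: np.ndarray) -> float:
    m = np.mean(x)
    if abs(m) < 1e-15:
        return float("inf") if np.std(x) > 1e-15 else 0.0
    return float(np.std(x) / abs(m))


def screen_unit(cv_control: float, d_fr_per_intensity: list[float], manipulation: str) -> str:
    """Screen one unit; returns KEEP, PV_TAGGED or NONSELECTIVE.

    ``cv_control`` is the raw-rate circular variance in the control condition;
    ``d_fr_per_intensity`` the pooled fractional rate changes.  A unit whose
    rate increases under PV activation (or decreases under PV inactivation)
    at a majority of intensities is an opsin-tagged PV+ cell.
    """
    if manipulation not in ("PVA", "PVI"):
        raise ValueError("manipulation must be PVA or PVI")
    if not d_fr_per_intensity:
        raise ValueError("need at least one intensity-level dFr")
    if cv_control > CV_SCREEN:
        return "NONSELECTIVE"
    signs = np.sign(d_fr_per_intensity)
    tagged_sign = 1.0 if manipulation == "PVA" else -1.0
    if np.sum(signs == tagged_sign) > len(d_fr_per_intensity) / 2:
        return "PV_TAGGED"
    return "KEEP"


def multiplicative_ratio(
    fr_c_p: float, fr_c_np: float, fr_l_p: float, fr_l_np: float
) -> float:
    """MR = FrC_NP/FrC_P - FrL_NP/FrL_P; near zero for pure gain changes."""
    if fr_c_p <= 0 or fr_l_p <= 0:
        raise ValueError("preferred-orientation rates must be positive")
    return fr_c_np / fr_c_p - fr_l_np / fr_l_p


def effect_curves(t_high: TuningCurve, t_low: TuningCurve) -> EffectCurves:
    """dT/RT curves and their statistics from high/low fitted curves on a grid.

    Both inputs must be fitted-curve evaluations on the same dense grid.  RT
    is masked (NaN) where the high-rate curve falls below the rate floor;
    CoV(RT) is computed over the unmasked points only.  The preferred and
    non-preferred orientations for MR are taken from the high-rate curve.
    """
    if t_high.directions.shape != t_low.directions.shape or not np.allclose(
        t_high.directions, t_low.directions
    ):
        raise ValueError("curves must share a common grid")
    grid = t_high.directions
    hi = t_high.mean_rate
    lo = t_low.mean_rate
    delta_t = lo - hi
    valid = hi >= RT_RATE_FLOOR_HZ
    if not np.any(valid):
        raise ValueError("high-rate curve entirely below the RT rate floor")
    ratio_t = np.where(valid, lo / np.where(valid, hi, 1.0), np.nan)

    i_p = int(np.argmax(hi))
    i_np = int(np.argmin(hi))
    mr = multiplicative_ratio(hi[i_p], hi[i_np], lo[i_p], lo[i_np])
    return EffectCurves(
        grid=grid,
        delta_t=delta_t,
        ratio_t=ratio_t,
        cov_delta_t=_cov(delta_t),
        cov_ratio_t=_cov(ratio_t[valid]),
        mr=mr,
    )


def _dt_derivatives(
    fit_high: VonMisesFit, fit_low: VonMisesFit, theta_p: float, h: float = 1.0
) -> tuple[float, float]:
    """Normalised 2nd/4th derivatives of dT at theta_p.

    Central finite differences of the smooth dT (difference of the fitted
    curves), divided by the magnitude of the matching derivative of the
    high-rate curve.  For any smooth control-to-laser map f the curvature of
    dT at the peak equals (f' - 1) times the curvature of the high-rate
    curve, so the normalised statistic is scale-free: it equals gain - 1 for
    a pure gain change (positive, since the peak curvature is negative) and
    has the opposite sign for a tuned, sharpening effect.
    """
    offsets = np.arange(-3, 4) * h
    hi = np.asarray(fit_high.evaluate(theta_p + offsets))
    lo = np.asarray(fit_low.evaluate(theta_p + offsets))
    dt = lo - hi

    def d2(v: np.ndarray) -> float:
        return float(v[2] - 2 * v[3] + v[4]) / h**2

    def d4(v: np.ndarray) -> float:
        return float(v[1] - 4 * v[2] + 6 * v[3] - 4 * v[4] + v[5]) / h**4

    d2h, d4h = d2(hi), d4(hi)
    n2 = d2(dt) / max(abs(d2h), 1e-12)
    n4 = d4(dt) / max(abs(d4h), 1e-12)
    return n2, n4


def classify_intensity(
    curves: EffectCurves,
    fit_high: VonMisesFit,
    fit_low: VonMisesFit,
    mr_threshold: float = MR_THRESHOLD,
    curvature_tol: float = 0.1,
    quartic_tol: float = 0.05,
) -> str:
    """Label one intensity as DM, NL or OTHER from the dT profile at theta_P.

    Second and fourth derivatives of the smooth dT (difference of the fitted
    curves) are evaluated at the preferred orientation of the high-rate fit,
    normalised by the matching derivatives of the high-rate curve so the sign
    tests are scale-free.  An upward dT peak (negative second derivative) or
    a flat-topped dT (positive second and fourth derivatives) is NL; a
    downward peak goes to the multiplicative-ratio test and is DM when
    |MR| < ``mr_threshold``, else OTHER.  ``curvature_tol`` and
    ``quartic_tol`` set the dead zone within which a derivative is treated
    as zero (flat).  An everywhere-flat dT (no measurable effect) is OTHER.
    """
    if np.max(np.abs(curves.delta_t)) < FLAT_DT_TOL_HZ:
        return "OTHER"
    theta_p, _, _, _ = preferred_orientations(fit_high)
    n2, n4 = _dt_derivatives(fit_high, fit_low, theta_p)
    if n2 < -curvature_tol:
        return "NL"
    if n4 > quartic_tol:
        # flat or downward-ambiguous top with a quartic upward shape
        return "NL"
    if abs(curves.mr) < mr_threshold:
        return "DM"
    return "OTHER"


def consolidate_unit(per_intensity: dict[str, str], waveform_matched: bool = True) -> str:
    """Consolidate per-intensity labels into a unit label.

    DM or NL requires unanimity across intensities (and matched waveforms);
    a mixture of DM and NL labels is MIX; anything else is UCT.
    """
    if not per_intensity:
        raise ValueError("need at least one per-intensity label")
    labels = set(per_intensity.values())
    if not waveform_matched:
        return "UCT"
    if labels == {"DM"}:
        return "DM"
    if labels == {"NL"}:
        return "NL"
    if {"DM", "NL"} <= labels:
        return "MIX"
    return "UCT"
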