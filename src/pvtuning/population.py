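"""Population-level statistics of laser-induced tuning changes.

Effect sizes are laser-minus-control differences (dFr as a fraction, dHBW in
degrees, dOSI and dCV dimensionless).  Units recorded at several laser
intensities enter the population as independent rows.  The module provides
the dFr magnitude binning (L/M/H/XH), metric-vs-dFr linear regressions,
paired Wilcoxon tests, peak-normalised population-averaged tuning curves and
per-layer summaries.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .tuning import TuningCurve

__all__ = [
    "RegressionResult",
    "bin_by_effect",
    "metric_regression",
    "paired_test",
    "population_average",
    "layer_summary",
]


@dataclass
class RegressionResult:
    """Pearson correlation plus ordinary least-squares line."""

    r: float
    p: float
    slope: float
    intercept: float
    n: int


def bin_by_effect(d_fr: float) -> str:
    """Bin a fractional rate change by magnitude: L, M, H or XH.

    L: 0 to +/-33%, M: +/-33 to +/-66%, H: +/-66 to +/-100%; XH (beyond
    +100%) exists only for rate increases (the PV-inactivation regime).
    """
    if not np.isfinite(d_fr):
        raise ValueError("d_fr must be finite")
    if d_fr > 1.0:
        return "XH"
    a = abs(d_fr)
    if a <= 1.0 / 3.0:
        return "L"
    if a <= 2.0 / 3.0:
        return "M"
    return "H"


def metric_regression(
    d_metric: np.ndarray, d_fr: np.ndarray, cluster: np.ndarray | None = None
) -> RegressionResult:
    """Pearson correlation and OLS line of a tuning-metric change on dFr.

    By default repeated measurements of the same unit at different
    intensities count as independent samples.  Passing per-row ``cluster``
    ids (e.g. unit ids) instead computes a cluster-robust (CR1 sandwich)
    standard error for the slope and a t-test on n_clusters - 1 degrees of
    freedom, for sensitivity analyses of that independence assumption.
    """
    x = np.asarray(d_fr, dtype=float)
    y = np.asarray(d_metric, dtype=float)
    ok = np.isfinite(x) & np.isfinite(y)
    if cluster is not None:
        cluster = np.asarray(cluster)[ok]
    x, y = x[ok], y[ok]
    if x.size < 3:
        raise ValueError("need at least 3 finite pairs")
    if np.ptp(x) < 1e-15:
        raise ValueError("constant d_fr: regression undefined")
    lr = stats.linregress(x, y)
    p = float(lr.pvalue)
    if cluster is not None:
        xc = x - x.mean()
        resid = y - (lr.slope * x + lr.intercept)
        sxx = float(np.sum(xc**2))
        groups = np.unique(cluster)
        g = groups.size
        if g < 3:
            raise ValueError("need at least 3 clusters")
        meat = sum(float(np.sum(xc[cluster == gr] * resid[cluster == gr])) ** 2
                   for gr in groups)
        se = np.sqrt(g / (g - 1) * meat) / sxx
        t = lr.slope / se if se > 0 else np.inf
        p = float(2.0 * stats.t.sf(abs(t), df=g - 1))
    return RegressionResult(
        r=float(lr.rvalue),
        p=p,
        slope=float(lr.slope),
        intercept=float(lr.intercept),
        n=int(x.size),
    )


def paired_test(values_control: np.ndarray, values_laser: np.ndarray) -> float:
    """Two-sided Wilcoxon signed-rank p-value for paired condition values.

    Returns 1.0 when every within-pair difference is zero (no signal).
    """
    a = np.asarray(values_control, dtype=float)
    b = np.asarray(values_laser, dtype=float)
    if a.size != b.size or a.size < 5:
        raise ValueError("need >= 5 paired observations")
    if np.allclose(a, b):
        return 1.0
    return float(stats.wilcoxon(a, b).pvalue)


def population_average(
    curves: list[TuningCurve],
    normalize: bool = True,
    align: bool = True,
    align_to: list[float] | None = None,
    grid_step: float = 1.0,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Mean +/- SEM population tuning curve on a common direction grid.

    Each curve is optionally normalised to its own peak and circularly
    shifted so its preferred direction maps to 0 degrees.  ``align_to``
    supplies per-curve alignment angles (e.g. the control-condition
    preferred orientation for both conditions of a unit); by default each
    curve is aligned on its own argmax.  Returns (grid, mean, sem).
    """
    if len(curves) < 2:
        raise ValueError("need at least 2 curves")
    if align_to is not None and len(align_to) != len(curves):
        raise ValueError("align_to must give one angle per curve")
    grid = np.arange(0.0, 360.0, grid_step)
    rows = np.empty((len(curves), grid.size))
    for i, c in enumerate(curves):
        rates = np.asarray(c.mean_rate, dtype=float)
        if normalize:
            peak = rates.max()
            if peak <= 0:
                raise ValueError("cannot normalise an all-zero curve")
            rates = rates / peak
        shift = 0.0
        if align:
            shift = (
                align_to[i]
                if align_to is not None
                else float(c.directions[int(np.argmax(rates))])
            )
        src = (grid + shift) % 360.0
        # periodic linear interpolation on the curve's own grid
        d = np.concatenate([c.directions, [c.directions[0] + 360.0]])
        r = np.concatenate([rates, [rates[0]]])
        rows[i] = np.interp(src, d, r)
    mean = rows.mean(axis=0)
    sem = rows.std(axis=0, ddof=1) / np.sqrt(len(curves))
    return grid, mean, sem


def layer_summary(effects: pd.DataFrame) -> pd.DataFrame:
    """Per-layer summary of tuning-effect sizes, pooled across intensities.

    ``effects`` needs columns layer, d_fr, d_hbw, d_osi, d_cv plus the paired
    metric columns (hbw_control, hbw_laser, osi_control, osi_laser,
    cv_control, cv_laser) when present.  Empty layers yield a row with n = 0
    and null statistics.
    """
    rows = []
    for layer in ("SG", "G", "IG"):
        sub = effects[effects["layer"] == layer]
        row: dict[str, object] = {"layer": layer, "n": int(len(sub))}
        for m in ("d_fr", "d_hbw", "d_osi", "d_cv"):
            if len(sub):
                row[f"{m}_median"] = float(sub[m].median())
                row[f"{m}_mean"] = float(sub[m].mean())
                row[f"{m}_sd"] = float(sub[m].std())
            else:
                row[f"{m}_median"] = row[f"{m}_mean"] = row[f"{m}_sd"] = np.nan
        for m in ("hbw", "osi", "cv"):
            ctrl, las = f"{m}_control", f"{m}_laser"
            if len(sub) >= 5 and ctrl in sub and las in sub:
                row[f"{m}_p"] = paired_test(sub[ctrl].to_numpy(), sub[las].to_numpy())
            else:
                row[f"{m}_p"] = np.nan
        rows.append(row)
    return pd.DataFrame(rows)
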