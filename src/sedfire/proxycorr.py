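"""Rolling multi-proxy correlation on a common spline-resampled grid.

Irregularly sampled proxies (charcoal influx, VRI) and annually resolved
climate reconstructions (PDSI) are brought onto one regular grid — 20-year
spacing by default — with a cubic smoothing spline, standardized to
z-scores, and optionally sign-flipped so that dry PDSI, open VRI and high
charcoal all point the same way. Pearson correlations are then computed in
rolling windows advancing by the grid step, their two-sided p-values taken
from the t distribution with (n_window - 2) df, and adjusted for multiple
comparison with the Benjamini-Hochberg step-up procedure across all windows
of a pair. Maximal runs of adjusted-significant windows summarize where in
time two proxies covary.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy import interpolate, stats
from statsmodels.stats.multitest import multipletests

from .errors import InputError

__all__ = [
    "ProxySeries",
    "RollingCorrelationResult",
    "standardize",
    "orient",
    "spline_resample",
    "rolling_correlation",
    "adjust_bh",
    "significant_windows",
]


@dataclass(frozen=True)
class ProxySeries:
    """An (age, value) series in calBP with a label such as CHAR/VRI/PDSI."""

    ages: np.ndarray
    values: np.ndarray
    label: str = "other"

    def __post_init__(self) -> None:
        ages = np.asarray(self.ages, dtype=float)
        values = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "ages", ages)
        object.__setattr__(self, "values", values)
        if ages.shape != values.shape or ages.ndim != 1:
            raise InputError("ages and values must be 1-d arrays of equal length")
        if ages.size > 1 and not np.all(np.diff(ages) > 0):
            raise InputError("ages must be strictly increasing (duplicates forbidden)")
        if not np.all(np.isfinite(values)):
            raise InputError("proxy values must be finite")


@dataclass(frozen=True)
class RollingCorrelationResult:
    """Per-window Pearson correlations for one proxy pair."""

    pair: str  # e.g. "CHAR-PDSI"
    centers: np.ndarray  # window-center ages, calBP
    r: np.ndarray
    p: np.ndarray
    p_adj: np.ndarray
    window: float  # years
    step: float  # years


def standardize(series: ProxySeries) -> ProxySeries:
    """Z-score the series over its full length (sample SD, ddof=1)."""
    if series.values.size < 2:
        raise InputError("standardize needs at least 2 points")
    sd = series.values.std(ddof=1)
    if sd == 0:
        raise InputError(f"{series.label}: zero variance, cannot standardize")
    z = (series.values - series.values.mean()) / sd
    return replace(series, values=z)


def orient(series: ProxySeries, flip: bool) -> ProxySeries:
    """Multiply values by -1 when *flip* is true (used on PDSI and VRI so that
    dry, open and high-charcoal all plot upward)."""
    return replace(series, values=-series.values) if flip else series


def spline_resample(
    series: ProxySeries,
    step: float = 20.0,
    smoothing: float | None = None,
) -> ProxySeries:
    """Evaluate a cubic smoothing spline on a regular *step*-year grid.

    ``smoothing`` is the roughness penalty lambda of the penalized
    least-squares spline; ``None`` selects it by generalized
    cross-validation and ``0`` interpolates the data exactly. The grid spans
    only the observed age range — no extrapolation.
    """
    x, y = series.ages, series.values
    if x.size < 4:
        raise InputError("spline_resample needs at least 4 points")
    if smoothing is not None and smoothing < 0:
        raise InputError("smoothing penalty must be >= 0")
    start = np.ceil(x[0] / step) * step
    grid = np.arange(start, x[-1] + 1e-9, step)
    if grid.size == 0 or grid[0] < x[0] - 1e-9 or grid[-1] > x[-1] + 1e-9:
        raise InputError("resampling grid would leave the observed age range")
    if smoothing == 0:
        spl = interpolate.CubicSpline(x, y)
    else:
        spl = interpolate.make_smoothing_spline(x, y, lam=smoothing)
    return ProxySeries(ages=grid, values=spl(grid), label=series.label)


def _check_common_grid(x: ProxySeries, y: ProxySeries) -> float:
    if x.ages.shape != y.ages.shape or not np.allclose(x.ages, y.ages):
        raise InputError("series must share one regular age grid")
    spacing = np.diff(x.ages)
    if spacing.size == 0 or not np.allclose(spacing, spacing[0]):
        raise InputError("age grid must be regular")
    return float(spacing[0])


def _ar1(v: np.ndarray) -> float:
    v = v - v.mean()
    denom = float(v @ v)
    return float(v[:-1] @ v[1:]) / denom if denom > 0 else 0.0


def rolling_correlation(
    x: ProxySeries,
    y: ProxySeries,
    window: float = 200.0,
    step: float = 20.0,
    ar1_correction: bool = False,
) -> RollingCorrelationResult:
    """Windowed Pearson correlation of two proxies on a shared regular grid.

    *window* and *step* are in years; a 200-y window on a 20-y grid uses 10
    grid points per window. With ``ar1_correction`` the p-values use an
    AR(1) effective sample size n_eff = n (1 - r1x r1y)/(1 + r1x r1y)
    instead of the raw window length (serial correlation otherwise inflates
    apparent significance; the multiple-testing step does not fix that).
    """
    d = _check_common_grid(x, y)
    n_pts = int(round(window / d))
    if n_pts < 3:
        raise InputError("window must cover at least 3 grid points")
    n_pts = min(n_pts, x.ages.size)
    advance = max(int(round(step / d)), 1)
    centers, rs, ps = [], [], []
    for start in range(0, x.ages.size - n_pts + 1, advance):
        sl = slice(start, start + n_pts)
        xv, yv = x.values[sl], y.values[sl]
        r, p = stats.pearsonr(xv, yv)
        if ar1_correction:
            phi = _ar1(xv) * _ar1(yv)
            n_eff = n_pts * (1 - phi) / (1 + phi)
            if n_eff > 3 and abs(r) < 1:
                t = r * np.sqrt((n_eff - 2) / (1 - r * r))
                p = 2 * stats.t.sf(abs(t), df=n_eff - 2)
        centers.append(float(x.ages[sl].mean()))
        rs.append(float(r))
        ps.append(float(p))
    ps_arr = np.asarray(ps)
    return RollingCorrelationResult(
        pair=f"{x.label}-{y.label}",
        centers=np.asarray(centers),
        r=np.asarray(rs),
        p=ps_arr,
        p_adj=adjust_bh(ps_arr),
        window=float(window),
        step=float(step),
    )


def adjust_bh(p: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (monotone, capped at 1)."""
    p = np.asarray(p, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any(p < 0) or np.any(p > 1) or not np.all(np.isfinite(p)):
        raise InputError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def significant_windows(
    result: RollingCorrelationResult,
    alpha: float = 0.05,
) -> list[dict]:
    """Maximal runs of consecutive windows with adjusted p < alpha.

    Each run is reported with the window-center ages it spans and the mean
    Pearson r over the run.
    """
    sig = result.p_adj < alpha
    runs = []
    i = 0
    while i < sig.size:
        if sig[i]:
            j = i
            while j + 1 < sig.size and sig[j + 1]:
                j += 1
            runs.append({
                "start_calbp": float(result.centers[i]),
                "end_calbp": float(result.centers[j]),
                "mean_r": float(result.r[i:j + 1].mean()),
                "n_windows": j - i + 1,
            })
            i = j + 1
        else:
            i += 1
    return runs
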