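"""Age-depth chronology of a sediment core.

The package consumes a posterior-summary age-depth table (e.g. the median
chronology exported from a Bayesian Pb-210/C-14 model) rather than fitting
one: downstream math needs only calendar ages and sedimentation rates.

Ages are in calBP (calendar years before AD 1950; negative values postdate
1950), depths in centimetres below the sediment surface.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import ChronologyError, OutOfRangeError

__all__ = [
    "AgeDepthModel",
    "age_at_depth",
    "deposition_time",
    "sedimentation_rate",
    "calbp_to_ad",
    "ad_to_calbp",
]


@dataclass(frozen=True)
class AgeDepthModel:
    """Piecewise-linear age-depth curve through dated control points.

    Parameters
    ----------
    depths : array of float
        Control-point depths in cm, strictly increasing.
    ages : array of float
        Calibrated ages in calBP at those depths, non-decreasing.
    age_sd : array of float, optional
        1-sigma age uncertainty (years) per control point. Carried as
        metadata; not used in the deterministic interpolation.
    allow_extrapolation : bool
        If True, queries beyond the dated range use the terminal segment's
        constant rate instead of raising ``OutOfRangeError``.
    """

    depths: np.ndarray
    ages: np.ndarray
    age_sd: np.ndarray | None = None
    allow_extrapolation: bool = False

    def __post_init__(self) -> None:
        depths = np.asarray(self.depths, dtype=float)
        ages = np.asarray(self.ages, dtype=float)
        object.__setattr__(self, "depths", depths)
        object.__setattr__(self, "ages", ages)
        if depths.ndim != 1 or depths.size < 2:
            raise ChronologyError("age-depth model needs at least 2 control points")
        if ages.shape != depths.shape:
            raise ChronologyError("depths and ages must have equal length")
        if not np.all(np.diff(depths) > 0):
            raise ChronologyError("control-point depths must be strictly increasing")
        if not np.all(np.diff(ages) >= 0):
            raise ChronologyError("ages must be non-decreasing with depth")
        if self.age_sd is not None:
            sd = np.asarray(self.age_sd, dtype=float)
            if sd.shape != depths.shape or np.any(sd < 0):
                raise ChronologyError("age_sd must be non-negative, one per control point")
            object.__setattr__(self, "age_sd", sd)

    @property
    def segment_slopes(self) -> np.ndarray:
        """Deposition time (yr/cm) of each segment between control points."""
        return np.diff(self.ages) / np.diff(self.depths)

    def _check_range(self, depth: float) -> None:
        if self.allow_extrapolation:
            return
        if depth < self.depths[0] or depth > self.depths[-1]:
            raise OutOfRangeError(
                f"depth {depth} cm outside modelled range "
                f"[{self.depths[0]}, {self.depths[-1]}] cm"
            )


def age_at_depth(model: AgeDepthModel, depth: float) -> float:
    """Calendar age (calBP) at *depth*, by linear interpolation.

    Exact at control points. Raises :class:`OutOfRangeError` outside the
    dated range unless the model allows extrapolation, in which case the
    nearest segment's slope is extended.
    """
    model._check_range(depth)
    d, a = model.depths, model.ages
    if depth <= d[0]:
        return float(a[0] + (depth - d[0]) * model.segment_slopes[0])
    if depth >= d[-1]:
        return float(a[-1] + (depth - d[-1]) * model.segment_slopes[-1])
    return float(np.interp(depth, d, a))


def deposition_time(model: AgeDepthModel, depth: float) -> float:
    """Deposition time (yr/cm) at *depth*: the local slope of the age-depth
    curve.

    Within a segment this is the segment slope; exactly at an interior
    control point it is the mean of the two flanking segment slopes (a
    symmetric convention — the junction itself has no unique slope).
    """
    model._check_range(depth)
    d = model.depths
    slopes = model.segment_slopes
    if np.any(slopes <= 0) and _touches_degenerate(model, depth):
        raise ChronologyError(f"zero-duration segment at depth {depth} cm")
    idx_interior = np.nonzero(np.isclose(depth, d[1:-1]))[0]
    if idx_interior.size:
        i = int(idx_interior[0])  # slopes i and i+1 flank control point i+1
        return float(0.5 * (slopes[i] + slopes[i + 1]))
    if depth <= d[0]:
        return float(slopes[0])
    if depth >= d[-1]:
        return float(slopes[-1])
    seg = int(np.searchsorted(d, depth, side="right") - 1)
    return float(slopes[seg])


def _touches_degenerate(model: AgeDepthModel, depth: float) -> bool:
    d = model.depths
    slopes = model.segment_slopes
    seg = min(max(int(np.searchsorted(d, depth, side="right") - 1), 0), slopes.size - 1)
    if slopes[seg] <= 0:
        return True
    idx_interior = np.nonzero(np.isclose(depth, d[1:-1]))[0]
    if idx_interior.size:
        i = int(idx_interior[0])
        return slopes[i] <= 0 or slopes[i + 1] <= 0
    return False


def sedimentation_rate(model: AgeDepthModel, depth: float) -> float:
    """Sedimentation rate S (cm/yr) at *depth*: reciprocal deposition time."""
    dt = deposition_time(model, depth)
    if dt <= 0:
        raise ChronologyError(f"non-positive deposition time at depth {depth} cm")
    return 1.0 / dt


def calbp_to_ad(age_calbp: float) -> float:
    """Convert calBP (present = AD 1950) to a calendar year AD."""
    return 1950 - age_calbp


def ad_to_calbp(year_ad: float) -> float:
    """Convert a calendar year AD to calBP."""
    return 1950 - year_ad
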