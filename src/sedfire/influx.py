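"""Tracer-based concentrations and accumulation rates (influx).

Pollen concentration in a layer is estimated from the ratio of fossil
grains to exotic Lycopodium tracer spores counted on the same slide:
a known spike of ``tracer_added`` spores is dissolved in ``volume`` cm3 of
sediment, so

    C = (taxon_count / tracer_counted) * (tracer_added / volume)   [grains/cm3]

and the pollen accumulation rate for taxon i is

    PAR_i = C_i * S                                        [grains/cm2/yr]

with S the sedimentation rate in cm/yr. Macroscopic charcoal is counted
exhaustively in a fixed sample volume (1 cm3 by default), so its influx
needs no tracer.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np

from .chronology import AgeDepthModel, age_at_depth, sedimentation_rate
from .errors import ChronologyError, InputError, UndefinedConcentrationError

__all__ = [
    "LayerSample",
    "InfluxSeries",
    "concentration",
    "par",
    "charcoal_influx",
    "influx_series",
    "LOW_TRACER_THRESHOLD",
]

# Below this many tallied tracer spores the ratio estimator gets noisy and a
# warning is emitted (the simple ratio is still used; no bias correction).
LOW_TRACER_THRESHOLD = 50


@dataclass(frozen=True)
class LayerSample:
    """One sediment-core layer: counts and the sampling metadata behind them.

    ``taxon_counts`` map taxon name to grains tallied. Counts are stored as
    floats so that expectation-valued (noise-free) synthetic layers are
    representable; real tallies are integers.
    """

    depth: float
    volume: float
    taxon_counts: Mapping[str, float]
    tracer_counted: float
    tracer_added: float
    charcoal_count: float = 0.0
    charcoal_volume: float = 1.0  # cm3; contiguous 1-cm3 subsamples by convention

    def __post_init__(self) -> None:
        if self.volume <= 0:
            raise InputError(f"layer at {self.depth} cm: volume must be > 0")
        if self.tracer_added <= 0:
            raise InputError(f"layer at {self.depth} cm: tracer_added must be > 0")
        if self.tracer_counted < 0 or self.charcoal_count < 0:
            raise InputError(f"layer at {self.depth} cm: counts must be >= 0")
        if self.charcoal_volume <= 0:
            raise InputError(f"layer at {self.depth} cm: charcoal_volume must be > 0")
        if any(c < 0 for c in self.taxon_counts.values()):
            raise InputError(f"layer at {self.depth} cm: negative taxon count")


@dataclass
class InfluxSeries:
    """Accumulation-rate series for one taxon (or charcoal) over a core.

    ``gap_mask`` flags layers where the quantity was unmeasurable (zero
    tracer counted); values there are NaN, never silently zero.
    """

    label: str
    ages: np.ndarray  # calBP, strictly increasing
    values: np.ndarray  # per-cm2-per-year
    gap_mask: np.ndarray = field(default=None)  # True where undefined

    def __post_init__(self) -> None:
        self.ages = np.asarray(self.ages, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.gap_mask is None:
            self.gap_mask = np.zeros(self.ages.shape, dtype=bool)
        self.gap_mask = np.asarray(self.gap_mask, dtype=bool)
        if self.ages.size > 1 and not np.all(np.diff(self.ages) > 0):
            raise InputError("influx series ages must be strictly increasing")
        defined = self.values[~self.gap_mask]
        if np.any(defined < 0):
            raise InputError("influx values must be non-negative")


def concentration(sample: LayerSample, taxon: str) -> float:
    """Pollen concentration of *taxon* in grains/cm3 via the tracer ratio.

    Raises :class:`UndefinedConcentrationError` when no tracer spores were
    counted: the layer is unmeasurable and must be flagged, not zeroed.
    """
    if sample.tracer_counted == 0:
        raise UndefinedConcentrationError(
            f"layer at {sample.depth} cm: zero tracer spores counted"
        )
    if sample.tracer_counted < LOW_TRACER_THRESHOLD:
        warnings.warn(
            f"layer at {sample.depth} cm: only {sample.tracer_counted:g} tracer "
            "spores counted; concentration estimate is noisy",
            stacklevel=2,
        )
    count = float(sample.taxon_counts.get(taxon, 0.0))
    return (count / sample.tracer_counted) * (sample.tracer_added / sample.volume)


def par(conc: float, sed_rate: float) -> float:
    """Pollen accumulation rate: concentration (grains/cm3) times the
    sedimentation rate S (cm/yr)."""
    if sed_rate <= 0:
        raise ChronologyError(f"sedimentation rate must be > 0, got {sed_rate}")
    return conc * sed_rate


def charcoal_influx(sample: LayerSample, sed_rate: float) -> float:
    """Charcoal influx in particles/cm2/yr from an exhaustive particle count."""
    if sed_rate <= 0:
        raise ChronologyError(f"sedimentation rate must be > 0, got {sed_rate}")
    return (sample.charcoal_count / sample.charcoal_volume) * sed_rate


def influx_series(
    core: Sequence[LayerSample],
    model: AgeDepthModel,
    target: str,
) -> InfluxSeries:
    """Assemble the (age, influx) series for *target* over a whole core.

    *target* is a taxon name or the literal ``"charcoal"``. Layers whose
    pollen concentration is undefined (zero tracer) become flagged gaps.
    Output is ordered by age; layer depths must already be sorted.
    """
    depths = [s.depth for s in core]
    if any(b <= a for a, b in zip(depths, depths[1:])):
        raise InputError("core layers must be in strictly increasing depth order")
    ages, values, gaps = [], [], []
    for sample in core:
        age = age_at_depth(model, sample.depth)
        rate = sedimentation_rate(model, sample.depth)
        if target == "charcoal":
            val, gap = charcoal_influx(sample, rate), False
        else:
            try:
                val, gap = par(concentration(sample, target), rate), False
            except UndefinedConcentrationError:
                val, gap = np.nan, True
        ages.append(age)
        values.append(val)
        gaps.append(gap)
    return InfluxSeries(label=target, ages=np.asarray(ages),
                        values=np.asarray(values), gap_mask=np.asarray(gaps))
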