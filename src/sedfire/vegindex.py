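"""Vegetation response index (VRI).

The VRI contrasts shade-tolerant pollen (Pseudotsuga, Notholithocarpus)
against shade-intolerant pollen (Quercus, Pinus) in a single ratio computed
from raw counts:

    VRI = ((Pseudotsuga + Notholithocarpus) - (Quercus + Pinus))
          / (Pseudotsuga + Notholithocarpus + Quercus + Pinus)

Positive values indicate a more closed canopy (shade-tolerant dominance),
negative a more open canopy. The index is scale-invariant, so counts and
percentages give identical values. A layer where all four taxa are zero
carries no canopy information and is flagged as a gap rather than set to 0.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .chronology import AgeDepthModel, age_at_depth
from .errors import InputError
from .influx import LayerSample

__all__ = ["VRISeries", "vri", "vri_series", "TOLERANT_TAXA", "INTOLERANT_TAXA"]

TOLERANT_TAXA = ("pseudotsuga", "notholithocarpus")
INTOLERANT_TAXA = ("quercus", "pinus")


@dataclass
class VRISeries:
    """Per-layer VRI with the four component counts retained."""

    ages: np.ndarray  # calBP
    values: np.ndarray  # in [-1, 1]; NaN where undefined
    gap_mask: np.ndarray  # True where the four-taxon sum was 0
    components: list  # per layer: dict of the four resolved counts

    def __post_init__(self) -> None:
        self.ages = np.asarray(self.ages, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        self.gap_mask = np.asarray(self.gap_mask, dtype=bool)
        defined = self.values[~self.gap_mask]
        if defined.size and (np.any(defined < -1) or np.any(defined > 1)):
            raise InputError("VRI values must lie in [-1, 1]")


def vri(pseudotsuga: float, notholithocarpus: float, quercus: float, pinus: float) -> float:
    """VRI from the four component counts; NaN when all four are zero."""
    for c in (pseudotsuga, notholithocarpus, quercus, pinus):
        if c < 0:
            raise InputError("pollen counts must be >= 0")
    tolerant = pseudotsuga + notholithocarpus
    intolerant = quercus + pinus
    total = tolerant + intolerant
    if total == 0:
        return float("nan")
    return (tolerant - intolerant) / total


def _resolve_count(counts: Mapping[str, float], taxon: str) -> float:
    """Case-insensitive lookup, pooling every key whose name starts with the
    formula taxon (e.g. 'Pinus subg. Strobus' pools into Pinus)."""
    total = 0.0
    for name, c in counts.items():
        if name.strip().lower().startswith(taxon):
            total += c
    return total


def vri_series(
    core: Sequence[LayerSample],
    model: AgeDepthModel | None = None,
    ages: Sequence[float] | None = None,
) -> VRISeries:
    """Compute the VRI for every layer of a core.

    Ages come from *model* (via the layer depths) or are supplied directly.
    Taxon names resolve case-insensitively; a formula taxon absent from every
    layer is treated as zero with a warning.
    """
    if ages is None:
        if model is None:
            raise InputError("supply either an age-depth model or explicit ages")
        ages = [age_at_depth(model, s.depth) for s in core]
    all_names = {n.strip().lower() for s in core for n in s.taxon_counts}
    for taxon in TOLERANT_TAXA + INTOLERANT_TAXA:
        if core and not any(n.startswith(taxon) for n in all_names):
            warnings.warn(f"taxon {taxon!r} missing from all layers; counted as 0",
                          stacklevel=2)
    values, gaps, components = [], [], []
    for sample in core:
        comp = {t: _resolve_count(sample.taxon_counts, t)
                for t in TOLERANT_TAXA + INTOLERANT_TAXA}
        v = vri(comp["pseudotsuga"], comp["notholithocarpus"],
                comp["quercus"], comp["pinus"])
        values.append(v)
        gaps.append(not np.isfinite(v))
        components.append(comp)
    return VRISeries(ages=np.asarray(ages, dtype=float),
                     values=np.asarray(values, dtype=float),
                     gap_mask=np.asarray(gaps, dtype=bool),
                     components=components)
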