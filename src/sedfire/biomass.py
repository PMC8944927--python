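"""Predicted aboveground live (AGL) tree biomass from pollen influx.

Each major tree taxon carries a linear calibration mapping its pollen
accumulation rate to distance-weighted AGL biomass,

    b_i = a_i + m_i * PAR_i        [Mg/ha],

with a published standard error of the regression estimate per taxon. The
calibration is an external product (a companion vegetation-survey study);
it is consumed from a config file, never refit here.

Uncertainty in the summed biomass is propagated by Monte Carlo: in each of
``n_iter`` iterations an error term eps_i ~ Normal(0, se_i) is added per
taxon and the per-taxon estimates summed; the reported value is the mean of
the iterate totals and its SE is their standard deviation (the predictive
SE of the sum, √(Σ se_i²) in closed form for independent taxa).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np

from .errors import CalibrationError, InputError
from .influx import InfluxSeries

__all__ = [
    "CalibrationEntry",
    "CalibrationSet",
    "BiomassEstimate",
    "predict_taxon_biomass",
    "propagate_uncertainty",
    "biomass_series",
    "summarize_baseline",
    "DEFAULT_N_ITER",
]

DEFAULT_N_ITER = 10_000


@dataclass(frozen=True)
class CalibrationEntry:
    """Linear PAR -> biomass calibration for one taxon.

    intercept, se_regression in Mg/ha; slope in Mg/ha per (grains/cm2/yr).
    """

    intercept: float
    slope: float
    se_regression: float

    def __post_init__(self) -> None:
        if self.se_regression < 0:
            raise CalibrationError("se_regression must be >= 0")


class CalibrationSet(dict):
    """Mapping taxon -> :class:`CalibrationEntry`; raises a named error on
    unknown taxa so a missing calibration is never a silent KeyError."""

    def __missing__(self, taxon: str) -> CalibrationEntry:
        raise CalibrationError(f"no calibration entry for taxon {taxon!r}")

    @classmethod
    def from_dict(cls, entries: Mapping[str, Mapping[str, float]]) -> "CalibrationSet":
        return cls({
            taxon: CalibrationEntry(
                intercept=float(e["intercept"]),
                slope=float(e["slope"]),
                se_regression=float(e["se_regression"]),
            )
            for taxon, e in entries.items()
        })


@dataclass(frozen=True)
class BiomassEstimate:
    """Summed AGL biomass at one layer age with Monte-Carlo uncertainty."""

    age: float  # calBP
    mean_total: float  # Mg/ha
    se_total: float  # Mg/ha, SD across MC iterations
    per_taxon_means: Mapping[str, float]
    iterations: int
    floored_taxa: tuple[str, ...] = ()  # taxa whose raw prediction was negative


def predict_taxon_biomass(par_value: float, entry: CalibrationEntry) -> tuple[float, bool]:
    """Point prediction b = intercept + slope * PAR, floored at zero.

    Returns ``(biomass, floored)`` where *floored* records that the raw
    linear prediction was negative (biomass cannot be), so the caller can
    flag it rather than lose the information.
    """
    if par_value < 0:
        raise InputError(f"PAR must be >= 0, got {par_value}")
    raw = entry.intercept + entry.slope * par_value
    return (max(raw, 0.0), raw < 0.0)


def propagate_uncertainty(
    par_by_taxon: Mapping[str, float],
    calib: CalibrationSet,
    n_iter: int = DEFAULT_N_ITER,
    seed: int | np.random.SeedSequence | None = None,
    age: float = np.nan,
) -> BiomassEstimate:
    """Monte-Carlo propagate per-taxon calibration error into the summed
    biomass for one layer.

    Per iteration the total is sum_i (b_i + eps_i), eps_i ~ N(0, se_i)
    independent across taxa and iterations. Taxa are processed in sorted
    name order so that the result is invariant to input ordering under a
    fixed seed.
    """
    if not par_by_taxon:
        raise InputError("empty taxon set")
    if n_iter < 1:
        raise InputError("n_iter must be >= 1")
    taxa = sorted(par_by_taxon)
    preds, floored, ses = [], [], []
    for taxon in taxa:
        b, was_floored = predict_taxon_biomass(float(par_by_taxon[taxon]), calib[taxon])
        preds.append(b)
        ses.append(calib[taxon].se_regression)
        if was_floored:
            floored.append(taxon)
    preds_arr = np.asarray(preds)
    ses_arr = np.asarray(ses)
    det_total = float(preds_arr.sum())
    if np.all(ses_arr == 0):
        # noise-free: mean is the deterministic sum, SE exactly zero
        mean_total, se_total = det_total, 0.0
    else:
        rng = np.random.default_rng(seed)
        eps = rng.standard_normal((n_iter, len(taxa))) * ses_arr
        totals = det_total + eps.sum(axis=1)
        mean_total = float(totals.mean())
        se_total = float(totals.std(ddof=1)) if n_iter > 1 else 0.0
    return BiomassEstimate(
        age=age,
        mean_total=mean_total,
        se_total=se_total,
        per_taxon_means=dict(zip(taxa, preds_arr)),
        iterations=n_iter,
        floored_taxa=tuple(floored),
    )


def biomass_series(
    influx_by_taxon: Mapping[str, InfluxSeries],
    calib: CalibrationSet,
    n_iter: int = DEFAULT_N_ITER,
    seed: int | None = None,
) -> list[BiomassEstimate]:
    """One biomass estimate per layer age, summed over taxa.

    All taxon series must share the same age grid. Each layer gets its own
    child seed spawned from *seed*, so dropping or reordering layers does
    not reshuffle the noise of the remaining ones.
    """
    if not influx_by_taxon:
        raise InputError("no taxon influx series supplied")
    series = list(influx_by_taxon.values())
    ages = series[0].ages
    for s in series[1:]:
        if s.ages.shape != ages.shape or not np.allclose(s.ages, ages):
            raise InputError("all taxon influx series must share one age grid")
    root = np.random.SeedSequence(seed)
    layer_seeds = root.spawn(len(ages))
    out = []
    for j, (age, ss) in enumerate(zip(ages, layer_seeds)):
        par_by_taxon = {}
        for taxon, s in influx_by_taxon.items():
            if s.gap_mask[j]:
                continue  # unmeasurable layer for this taxon: excluded, not zero
            par_by_taxon[taxon] = float(s.values[j])
        out.append(propagate_uncertainty(par_by_taxon, calib, n_iter=n_iter,
                                         seed=ss, age=float(age)))
    return out


def summarize_baseline(
    series: Sequence[BiomassEstimate],
    age_window: tuple[float, float],
) -> dict:
    """Median and interquartile range of mean biomass over the layers whose
    age falls inside *age_window* (calBP, inclusive bounds)."""
    lo, hi = min(age_window), max(age_window)
    vals = np.asarray([e.mean_total for e in series if lo <= e.age <= hi])
    if vals.size == 0:
        raise InputError(f"no samples inside age window [{lo}, {hi}] calBP")
    q25, q50, q75 = np.percentile(vals, [25, 50, 75])
    return {"median": float(q50), "iqr": (float(q25), float(q75)), "n": int(vals.size)}
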