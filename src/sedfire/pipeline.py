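"""End-to-end orchestration: from raw input files to result tables.

A :class:`RunConfig` captures every input path and analysis setting of one
run; :func:`run_pipeline` executes the stages in order — influx, biomass,
VRI, rolling correlations, fire history — writing one CSV per product plus
a JSON manifest (input hashes, seed, settings) so a run can be reproduced
from its archived config and inputs alone.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import io as sfio
from .biomass import DEFAULT_N_ITER, biomass_series, summarize_baseline
from .errors import InputError, SedfireError
from .firehistory import composite, median_fri, seasonality_summary
from .influx import influx_series
from .proxycorr import (ProxySeries, orient, rolling_correlation,
                        significant_windows, spline_resample, standardize)
from .vegindex import vri_series

__all__ = ["RunConfig", "run_pipeline"]


@dataclass
class RunConfig:
    """Inputs and settings of one pipeline run; fully serializable."""

    age_depth_path: str
    pollen_path: str
    layers_path: str
    calibration_path: str
    pdsi_path: str
    output_dir: str
    fhx_path: str | None = None  # FHX2 alternative to the CSV pair
    trees_path: str | None = None
    scar_events_path: str | None = None
    taxa: list[str] = field(default_factory=list)  # empty = all calibrated taxa
    n_iter: int = DEFAULT_N_ITER
    seed: int = 0
    spline_step: float = 20.0
    spline_smoothing: float | None = None  # None = GCV
    corr_window: float = 200.0
    corr_step: float = 20.0
    alpha: float = 0.05
    ar1_correction: bool = False
    min_trees: int = 2
    min_depth: int = 2
    fri_period: tuple[int, int] = (1700, 1900)
    baseline_window: tuple[float, float] | None = None  # calBP

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path, encoding="utf-8") as fh:
            raw = yaml.safe_load(fh)
        cfg = cls(**raw)
        if isinstance(cfg.fri_period, list):
            cfg.fri_period = tuple(cfg.fri_period)
        if isinstance(cfg.baseline_window, list):
            cfg.baseline_window = tuple(cfg.baseline_window)
        return cfg

    def to_yaml(self, path: str | Path) -> None:
        data = dataclasses.asdict(self)
        data["fri_period"] = list(self.fri_period)
        if self.baseline_window is not None:
            data["baseline_window"] = list(self.baseline_window)
        with open(path, "w", encoding="utf-8") as fh:
            yaml.safe_dump(data, fh, sort_keys=False)


def _sha256(path: str | Path) -> str:
    h = hashlib.sha256()
    h.update(Path(path).read_bytes())
    return h.hexdigest()


def _stage(name: str):
    """Label exceptions with the pipeline stage that raised them."""
    class _Ctx:
        def __enter__(self):
            return self

        def __exit__(self, exc_type, exc, tb):
            if exc is not None and isinstance(exc, Exception):
                raise SedfireError(f"stage {name!r} failed: {exc}") from exc
    return _Ctx()


def run_pipeline(config: RunConfig) -> dict:
    """Run every analysis stage and write the result bundle.

    Returns a dict with the in-memory results and the paths written.
    """
    out_dir = Path(config.output_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    results: dict = {"outputs": {}}

    with _stage("load"):
        for label, p in [("age_depth", config.age_depth_path),
                         ("pollen", config.pollen_path),
                         ("layers", config.layers_path),
                         ("calibration", config.calibration_path),
                         ("pdsi", config.pdsi_path)]:
            if not Path(p).exists():
                raise InputError(f"required input {label!r} not found at {p}")
        model = sfio.read_age_depth_csv(config.age_depth_path)
        core = sfio.read_core_csv(config.pollen_path, config.layers_path)
        calib = sfio.read_calibration(config.calibration_path)
        pdsi = sfio.read_pdsi_csv(config.pdsi_path)

    taxa = list(config.taxa) or sorted(calib)

    with _stage("influx"):
        influx_by_taxon = {t: influx_series(core, model, t) for t in taxa}
        char = influx_series(core, model, "charcoal")
        sfio.write_influx_csv(char, out_dir / "charcoal_influx.csv")
        results["outputs"]["charcoal_influx"] = str(out_dir / "charcoal_influx.csv")
        results["charcoal"] = char

    with _stage("biomass"):
        bio = biomass_series(influx_by_taxon, calib,
                             n_iter=config.n_iter, seed=config.seed)
        sfio.write_biomass_csv(bio, out_dir / "biomass.csv")
        results["outputs"]["biomass"] = str(out_dir / "biomass.csv")
        results["biomass"] = bio
        if config.baseline_window is not None:
            results["baseline"] = summarize_baseline(bio, config.baseline_window)

    with _stage("vri"):
        vri = vri_series(core, model=model)
        sfio.write_vri_csv(vri, out_dir / "vri.csv")
        results["outputs"]["vri"] = str(out_dir / "vri.csv")
        results["vri"] = vri

    with _stage("correlate"):
        ok = ~char.gap_mask & np.isfinite(char.values)
        char_p = ProxySeries(ages=char.ages[ok], values=char.values[ok], label="CHAR")
        okv = ~vri.gap_mask
        vri_p = ProxySeries(ages=vri.ages[okv], values=vri.values[okv], label="VRI")
        prepared = {}
        for series, flip in [(char_p, False), (vri_p, True), (pdsi, True)]:
            res = spline_resample(series, step=config.spline_step,
                                  smoothing=config.spline_smoothing)
            prepared[series.label] = standardize(orient(res, flip))
        results["correlations"] = {}
        for a, b in [("CHAR", "PDSI"), ("CHAR", "VRI"), ("PDSI", "VRI")]:
            xa, xb = prepared[a], prepared[b]
            lo = max(xa.ages[0], xb.ages[0])
            hi = min(xa.ages[-1], xb.ages[-1])
            ma = (xa.ages >= lo) & (xa.ages <= hi)
            mb = (xb.ages >= lo) & (xb.ages <= hi)
            xa = ProxySeries(ages=xa.ages[ma], values=xa.values[ma], label=a)
            xb = ProxySeries(ages=xb.ages[mb], values=xb.values[mb], label=b)
            rc = rolling_correlation(xa, xb, window=config.corr_window,
                                     step=config.corr_step,
                                     ar1_correction=config.ar1_correction)
            path = out_dir / f"correlation_{a}_{b}.csv"
            sfio.write_correlation_csv(rc, path)
            results["outputs"][f"correlation_{a}_{b}"] = str(path)
            results["correlations"][rc.pair] = {
                "result": rc,
                "significant": significant_windows(rc, alpha=config.alpha),
            }

    with _stage("firehist"):
        if config.fhx_path:
            scars = sfio.read_fhx(config.fhx_path)
        elif config.trees_path and config.scar_events_path:
            scars = sfio.read_scars_csv(config.trees_path, config.scar_events_path)
        else:
            scars = None
        if scars is not None:
            comp = composite(scars, min_trees=config.min_trees,
                             min_depth=config.min_depth)
            results["fire"] = {
                "composite": comp,
                "median_fri": median_fri(comp, config.fri_period),
                "median_fri_all_years": median_fri(comp),
                "seasonality": seasonality_summary(scars),
            }
            comp_path = out_dir / "fire_composite.csv"
            import pandas as pd
            pd.DataFrame({
                "fire_year_ad": comp.fire_years,
                "trees_scarred": [comp.trees_scarred[y] for y in comp.fire_years],
                "sample_depth": [comp.depth[y] for y in comp.fire_years],
            }).to_csv(comp_path, index=False)
            results["outputs"]["fire_composite"] = str(comp_path)

    with _stage("manifest"):
        manifest = {
            "seed": config.seed,
            "n_iter": config.n_iter,
            "settings": {k: v for k, v in dataclasses.asdict(config).items()
                         if not k.endswith("_path") and k != "output_dir"},
            "inputs": {},
        }
        for name in ("age_depth_path", "pollen_path", "layers_path",
                     "calibration_path", "pdsi_path", "fhx_path",
                     "trees_path", "scar_events_path"):
            p = getattr(config, name)
            if p and Path(p).exists():
                manifest["inputs"][name] = {"path": str(p), "sha256": _sha256(p)}
        with open(out_dir / "manifest.json", "w", encoding="utf-8") as fh:
            json.dump(manifest, fh, indent=2, default=str)
        results["outputs"]["manifest"] = str(out_dir / "manifest.json")

    return results
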