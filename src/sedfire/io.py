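"""Readers and writers for the pipeline's interchange formats.

CSV dialect: comma-separated, UTF-8, required headers, "." decimal.
Fire-scar data travel either as a pair of CSVs (trees + scars) or as FHX2,
the fire-history exchange format: a header naming the first year, sample
count and id length; sample ids written vertically; then one row per year
whose columns hold '{'/'}' at span ends, an uppercase season letter at a
scar, '|' for a recording year without fire, and '.' outside the span.
"""

from __future__ import annotations

import io as _io
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from .biomass import BiomassEstimate, CalibrationEntry, CalibrationSet
from .chronology import AgeDepthModel, ad_to_calbp
from .errors import InputError
from .firehistory import SCAR_POSITIONS, FireScarDataset, TreeRecord
from .influx import InfluxSeries, LayerSample
from .proxycorr import ProxySeries, RollingCorrelationResult
from .vegindex import VRISeries

__all__ = [
    "read_age_depth_csv", "write_age_depth_csv",
    "read_core_csv", "write_core_csv",
    "read_calibration", "write_calibration",
    "read_pdsi_csv", "write_pdsi_csv",
    "read_scars_csv", "write_scars_csv",
    "read_fhx", "write_fhx",
    "write_biomass_csv", "write_vri_csv", "write_influx_csv", "write_correlation_csv",
]

# FHX2 season codes <-> intra-ring positions
_POS_TO_CODE = {
    "dormant": "D", "early-earlywood": "E", "middle-earlywood": "M",
    "late-earlywood": "L", "latewood": "A", "unknown": "U",
}
_CODE_TO_POS = {v: k for k, v in _POS_TO_CODE.items()}


def _require_columns(df: pd.DataFrame, cols: Sequence[str], what: str) -> None:
    missing = [c for c in cols if c not in df.columns]
    if missing:
        raise InputError(f"{what}: missing required column(s) {missing}")


# -- age-depth ---------------------------------------------------------------

def read_age_depth_csv(path: str | Path, **kwargs) -> AgeDepthModel:
    """Columns: depth_cm, age_calbp, optional age_sd_yr."""
    df = pd.read_csv(path)
    _require_columns(df, ["depth_cm", "age_calbp"], str(path))
    sd = df["age_sd_yr"].to_numpy(float) if "age_sd_yr" in df.columns else None
    return AgeDepthModel(depths=df["depth_cm"].to_numpy(float),
                         ages=df["age_calbp"].to_numpy(float),
                         age_sd=sd, **kwargs)


def write_age_depth_csv(model: AgeDepthModel, path: str | Path) -> None:
    data = {"depth_cm": model.depths, "age_calbp": model.ages}
    if model.age_sd is not None:
        data["age_sd_yr"] = model.age_sd
    pd.DataFrame(data).to_csv(path, index=False)


# -- core layers (pollen long CSV + layer metadata CSV) ----------------------

def read_core_csv(pollen_path: str | Path, layers_path: str | Path) -> list[LayerSample]:
    """Pollen CSV (long): depth_cm, taxon, count.
    Layer CSV: depth_cm, volume_cm3, tracer_counted, tracer_added,
    charcoal_count, optional charcoal_volume_cm3."""
    pollen = pd.read_csv(pollen_path)
    layers = pd.read_csv(layers_path)
    _require_columns(pollen, ["depth_cm", "taxon", "count"], str(pollen_path))
    _require_columns(layers, ["depth_cm", "volume_cm3", "tracer_counted",
                              "tracer_added", "charcoal_count"], str(layers_path))
    counts_by_depth = {
        depth: dict(zip(grp["taxon"], grp["count"].astype(float)))
        for depth, grp in pollen.groupby("depth_cm")
    }
    out = []
    for _, row in layers.sort_values("depth_cm").iterrows():
        depth = float(row["depth_cm"])
        out.append(LayerSample(
            depth=depth,
            volume=float(row["volume_cm3"]),
            taxon_counts=counts_by_depth.get(depth, {}),
            tracer_counted=float(row["tracer_counted"]),
            tracer_added=float(row["tracer_added"]),
            charcoal_count=float(row["charcoal_count"]),
            charcoal_volume=(float(row["charcoal_volume_cm3"])
                             if "charcoal_volume_cm3" in row
                             and pd.notna(row["charcoal_volume_cm3"]) else 1.0),
        ))
    return out


def write_core_csv(core: Sequence[LayerSample],
                   pollen_path: str | Path, layers_path: str | Path) -> None:
    pollen_rows = [
        {"depth_cm": s.depth, "taxon": t, "count": c}
        for s in core for t, c in sorted(s.taxon_counts.items())
    ]
    layer_rows = [
        {"depth_cm": s.depth, "volume_cm3": s.volume,
         "tracer_counted": s.tracer_counted, "tracer_added": s.tracer_added,
         "charcoal_count": s.charcoal_count, "charcoal_volume_cm3": s.charcoal_volume}
        for s in core
    ]
    pd.DataFrame(pollen_rows).to_csv(pollen_path, index=False)
    pd.DataFrame(layer_rows).to_csv(layers_path, index=False)


# -- calibration -------------------------------------------------------------

def read_calibration(path: str | Path) -> CalibrationSet:
    """CSV (taxon, intercept, slope, se_regression) or a YAML mapping."""
    path = Path(path)
    if path.suffix.lower() in {".yml", ".yaml"}:
        with open(path, encoding="utf-8") as fh:
            data = yaml.safe_load(fh)
        return CalibrationSet.from_dict(data)
    df = pd.read_csv(path)
    _require_columns(df, ["taxon", "intercept", "slope", "se_regression"], str(path))
    out = CalibrationSet()
    for _, row in df.iterrows():
        out[str(row["taxon"])] = CalibrationEntry(
            intercept=float(row["intercept"]), slope=float(row["slope"]),
            se_regression=float(row["se_regression"]))
    return out


def write_calibration(calib: CalibrationSet, path: str | Path) -> None:
    rows = [{"taxon": t, "intercept": e.intercept, "slope": e.slope,
             "se_regression": e.se_regression} for t, e in sorted(calib.items())]
    pd.DataFrame(rows).to_csv(path, index=False)


# -- PDSI --------------------------------------------------------------------

def read_pdsi_csv(path: str | Path) -> ProxySeries:
    """Columns: pdsi plus either age_calbp or year_ad."""
    df = pd.read_csv(path)
    _require_columns(df, ["pdsi"], str(path))
    if "age_calbp" in df.columns:
        ages = df["age_calbp"].to_numpy(float)
    elif "year_ad" in df.columns:
        ages = ad_to_calbp(df["year_ad"].to_numpy(float))
    else:
        raise InputError(f"{path}: need an age_calbp or year_ad column")
    order = np.argsort(ages)
    return ProxySeries(ages=ages[order], values=df["pdsi"].to_numpy(float)[order],
                       label="PDSI")


def write_pdsi_csv(series: ProxySeries, path: str | Path) -> None:
    pd.DataFrame({"age_calbp": series.ages, "pdsi": series.values}).to_csv(
        path, index=False)


# -- fire scars: CSV pair ----------------------------------------------------

def read_scars_csv(trees_path: str | Path, scars_path: str | Path) -> FireScarDataset:
    """Trees CSV: tree_id, species, inner_year, outer_year.
    Scars CSV: tree_id, year, position."""
    trees = pd.read_csv(trees_path)
    scars = pd.read_csv(scars_path)
    _require_columns(trees, ["tree_id", "species", "inner_year", "outer_year"],
                     str(trees_path))
    _require_columns(scars, ["tree_id", "year", "position"], str(scars_path))
    scars_by_tree: dict[str, dict[int, str]] = {}
    for _, row in scars.iterrows():
        pos = str(row["position"]).strip().lower()
        if pos not in SCAR_POSITIONS:
            raise InputError(f"{scars_path}: unknown scar position {pos!r}")
        scars_by_tree.setdefault(str(row["tree_id"]), {})[int(row["year"])] = pos
    records = [
        TreeRecord(tree_id=str(row["tree_id"]), species=str(row["species"]),
                   inner_year=int(row["inner_year"]), outer_year=int(row["outer_year"]),
                   scars=scars_by_tree.get(str(row["tree_id"]), {}))
        for _, row in trees.iterrows()
    ]
    return FireScarDataset(trees=tuple(records))


def write_scars_csv(dataset: FireScarDataset,
                    trees_path: str | Path, scars_path: str | Path) -> None:
    tree_rows = [{"tree_id": t.tree_id, "species": t.species,
                  "inner_year": t.inner_year, "outer_year": t.outer_year}
                 for t in dataset.trees]
    scar_rows = [{"tree_id": tid, "year": y, "position": p}
                 for tid, y, p in dataset.all_scars()]
    pd.DataFrame(tree_rows).to_csv(trees_path, index=False)
    pd.DataFrame(scar_rows).to_csv(scars_path, index=False)


# -- fire scars: FHX2 --------------------------------------------------------

def write_fhx(dataset: FireScarDataset, path: str | Path) -> None:
    """Write the canonical FHX2 representation of a dataset."""
    trees = dataset.trees
    if not trees:
        raise InputError("cannot write an empty FHX2 file")
    first = min(t.inner_year for t in trees)
    last = max(t.outer_year for t in trees)
    ids = [t.tree_id for t in trees]
    id_len = max(len(i) for i in ids)
    lines = ["FHX2 FORMAT", f"{first} {len(trees)} {id_len}"]
    padded = [i.ljust(id_len) for i in ids]
    for row in range(id_len):
        lines.append("".join(p[row] for p in padded))
    lines.append("")
    for year in range(first, last + 1):
        cols = []
        for t in trees:
            if year < t.inner_year or year > t.outer_year:
                cols.append(".")
            elif year in t.scars:
                cols.append(_POS_TO_CODE[t.scars[year]])
            elif year == t.inner_year:
                cols.append("{")
            elif year == t.outer_year:
                cols.append("}")
            else:
                cols.append("|")
        lines.append("".join(cols) + f" {year}")
    Path(path).write_text("\n".join(lines) + "\n", encoding="utf-8")


def read_fhx(path: str | Path) -> FireScarDataset:
    """Parse an FHX2 file written by :func:`write_fhx` (and plain files in
    the same dialect). Malformed year rows raise with the line number."""
    text = Path(path).read_text(encoding="utf-8")
    lines = text.splitlines()
    try:
        header_idx = next(i for i, line in enumerate(lines)
                          if line.strip().upper().startswith("FHX2"))
    except StopIteration:
        raise InputError(f"{path}: no FHX2 FORMAT header") from None
    try:
        first_year, n_samples, id_len = map(int, lines[header_idx + 1].split())
    except (ValueError, IndexError):
        raise InputError(
            f"{path}: line {header_idx + 2}: expected 'first_year n_samples id_length'"
        ) from None
    id_rows = lines[header_idx + 2: header_idx + 2 + id_len]
    ids = ["".join(row[k] if k < len(row) else " " for row in id_rows).strip()
           for k in range(n_samples)]
    data_start = header_idx + 2 + id_len
    inner = [None] * n_samples
    outer = [None] * n_samples
    scars: list[dict[int, str]] = [dict() for _ in range(n_samples)]
    for lineno, line in enumerate(lines[data_start:], start=data_start + 1):
        if not line.strip():
            continue
        body, _, year_txt = line.rstrip().rpartition(" ")
        try:
            year = int(year_txt)
        except ValueError:
            raise InputError(f"{path}: line {lineno}: malformed year column "
                             f"{year_txt!r}") from None
        if len(body) < n_samples:
            body = body.ljust(n_samples, ".")
        for k in range(n_samples):
            ch = body[k]
            if ch == ".":
                continue
            if inner[k] is None:
                inner[k] = year
            outer[k] = year
            code = ch.upper()
            if code in _CODE_TO_POS and ch.isalpha():
                scars[k][year] = _CODE_TO_POS[code]
            elif ch not in "{}|[]_":
                raise InputError(f"{path}: line {lineno}: unknown symbol {ch!r}")
    records = []
    for k in range(n_samples):
        if inner[k] is None:
            raise InputError(f"{path}: sample {ids[k]!r} has no recording years")
        records.append(TreeRecord(tree_id=ids[k], species="UNKN",
                                  inner_year=inner[k], outer_year=outer[k],
                                  scars=scars[k]))
    return FireScarDataset(trees=tuple(records))


# -- result tables -----------------------------------------------------------

def write_biomass_csv(series: Sequence[BiomassEstimate], path: str | Path) -> None:
    taxa = sorted({t for e in series for t in e.per_taxon_means})
    rows = []
    for e in series:
        row = {"age_calbp": e.age, "biomass_mean_mgha": e.mean_total,
               "biomass_se_mgha": e.se_total}
        for t in taxa:
            row[t] = e.per_taxon_means.get(t, np.nan)
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, index=False)


def write_vri_csv(series: VRISeries, path: str | Path) -> None:
    rows = []
    for age, v, comp in zip(series.ages, series.values, series.components):
        rows.append({"age_calbp": age, "vri": v,
                     **{k: comp[k] for k in sorted(comp)}})
    pd.DataFrame(rows).to_csv(path, index=False)


def write_influx_csv(series: InfluxSeries, path: str | Path) -> None:
    pd.DataFrame({"age_calbp": series.ages,
                  f"{series.label}_influx": series.values,
                  "gap": series.gap_mask.astype(int)}).to_csv(path, index=False)


def write_correlation_csv(result: RollingCorrelationResult, path: str | Path) -> None:
    pd.DataFrame({"window_center_calbp": result.centers, "r": result.r,
                  "p": result.p, "p_adj": result.p_adj}).to_csv(path, index=False)
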