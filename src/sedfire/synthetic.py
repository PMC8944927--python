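"""Synthetic cores, climate series and fire-scar datasets with known truth.

Every generator emulates one input stream of the study design:

* a monotone age-depth table with lognormally varying sedimentation,
* tracer-spiked Poisson pollen counts driven by latent, smooth per-taxon
  biomass trajectories that obey the linear PAR-biomass calibration,
* macroscopic charcoal counts with Poisson background plus spikes in
  layers that contain a fire year,
* an annually resolved AR(1) drought index with imposed mean shifts in
  climate-anomaly windows (a dry MCA-like and a wet LIA-like excursion),
* a latent gamma-renewal fire-year process recorded imperfectly by a
  population of trees.

Each generator takes an explicit seed and returns the generated object
together with a truth record, so that recovery of the latent state by the
analysis pipeline is a testable property rather than a hope.

Default parameter values are the study-scale conditions: a ~3,000-year,
60-layer core sampled at 5-cm increments, 8 major tree taxa totalling
~130 Mg/ha, 0.625-cm3 pollen samples spiked with 20,000 tracer spores,
~300 tracer spores tallied per slide, and a fire regime with roughly
decadal return intervals recorded by a few dozen trees.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .biomass import CalibrationEntry, CalibrationSet
from .chronology import AgeDepthModel, age_at_depth, sedimentation_rate
from .errors import InputError
from .firehistory import SCAR_POSITIONS, FireScarDataset, TreeRecord
from .influx import LayerSample
from .proxycorr import ProxySeries

__all__ = [
    "SyntheticTruth",
    "default_calibration",
    "gen_age_depth",
    "gen_biomass_trajectories",
    "gen_core",
    "gen_fire_history",
    "gen_pdsi",
    "gen_correlated_proxies",
    "StudyBundle",
    "simulate_study",
    "write_study_inputs",
    "DEFAULT_TAXA",
    "DEFAULT_SEASON_MIX",
    "MCA_WINDOW",
    "LIA_WINDOW",
]

DEFAULT_TAXA = (
    "Pseudotsuga", "Notholithocarpus", "Quercus", "Pinus",
    "Chamaecyparis", "Abies", "Alnus", "Tsuga",
)

# calBP intervals of the two late-Holocene climate anomalies used as test
# windows: warm/dry Medieval Climate Anomaly, cool/wet Little Ice Age.
MCA_WINDOW = (850.0, 1200.0)
LIA_WINDOW = (50.0, 750.0)

DEFAULT_SEASON_MIX = {
    "latewood": 0.60,
    "dormant": 0.28,
    "late-earlywood": 0.05,
    "early-earlywood": 0.04,
    "middle-earlywood": 0.02,
    "unknown": 0.01,
}


@dataclass
class SyntheticTruth:
    """Latent state behind a synthetic dataset, for recovery tests."""

    seed: int | None = None
    params: dict = field(default_factory=dict)
    trajectories: dict | None = None  # taxon -> Mg/ha on the layer-age grid
    trajectory_ages: np.ndarray | None = None  # calBP
    fire_years: tuple | None = None  # calendar AD (tree data) or calBP (charcoal)
    sedimentation: np.ndarray | None = None  # cm/yr per segment
    anomaly_windows: tuple | None = None  # (lo_calbp, hi_calbp, shift)


def default_calibration(taxa: Sequence[str] = DEFAULT_TAXA) -> CalibrationSet:
    """A study-scale synthetic calibration table.

    Slopes and intercepts are order-of-magnitude realistic for temperate
    conifer/hardwood pollen (tens of Mg/ha per thousand grains/cm2/yr);
    per-taxon regression SEs of about 6 Mg/ha make calibration error the
    dominant uncertainty at realistic counting effort. This is a synthetic
    stand-in for an external vegetation-survey calibration, used by the
    generators and tests only.
    """
    base = {
        "Pseudotsuga": (2.0, 0.050, 7.0),
        "Notholithocarpus": (1.0, 0.040, 6.0),
        "Quercus": (1.5, 0.030, 5.0),
        "Pinus": (2.0, 0.020, 6.0),
        "Chamaecyparis": (0.5, 0.060, 5.0),
        "Abies": (1.0, 0.045, 6.0),
        "Alnus": (0.5, 0.015, 4.0),
        "Tsuga": (0.5, 0.055, 5.0),
    }
    out = CalibrationSet()
    for i, taxon in enumerate(taxa):
        inter, slope, se = base.get(taxon, (1.0, 0.03 + 0.005 * (i % 5), 5.0))
        out[taxon] = CalibrationEntry(intercept=inter, slope=slope, se_regression=se)
    return out


def gen_age_depth(
    n_controls: int = 13,
    total_depth: float = 300.0,
    age_span: float = 2900.0,
    rate_variability: float = 0.3,
    seed: int | None = None,
    age_top: float = -58.0,
) -> tuple[AgeDepthModel, SyntheticTruth]:
    """Monotone age-depth control points with lognormal segment-rate
    variation.

    Segment deposition times are lognormal around the mean rate and then
    rescaled so the core spans exactly *age_span* years below an *age_top*
    (a modern coring date, negative calBP). ``rate_variability`` is the
    lognormal sigma; 0 gives an exactly linear chronology.
    """
    if n_controls < 2:
        raise InputError("need at least 2 control points")
    rng = np.random.default_rng(seed)
    depths = np.linspace(0.0, total_depth, n_controls)
    seg_len = np.diff(depths)
    log_t = rng.normal(0.0, rate_variability, size=n_controls - 1)
    seg_time = seg_len * np.exp(log_t)  # yr per segment, up to scale
    seg_time *= age_span / seg_time.sum()
    ages = age_top + np.concatenate([[0.0], np.cumsum(seg_time)])
    model = AgeDepthModel(depths=depths, ages=ages)
    truth = SyntheticTruth(
        seed=seed,
        params=dict(n_controls=n_controls, total_depth=total_depth,
                    age_span=age_span, rate_variability=rate_variability,
                    age_top=age_top),
        sedimentation=seg_len / seg_time,  # cm/yr, per segment
    )
    return model, truth


def gen_biomass_trajectories(
    ages: np.ndarray,
    taxa: Sequence[str] = DEFAULT_TAXA,
    total_scale: float = 130.0,
    variability: float = 0.35,
    seed: int | None = None,
) -> dict[str, np.ndarray]:
    """Smooth, strictly positive latent biomass trajectories (Mg/ha).

    Each taxon follows a log-scale sum of three low-frequency sinusoids
    with random phases and amplitudes, around a fixed taxon base share of
    ``total_scale``. Millennial-scale smoothness mimics vegetation turnover
    rather than year-to-year noise.
    """
    rng = np.random.default_rng(seed)
    ages = np.asarray(ages, dtype=float)
    span = max(ages.max() - ages.min(), 1.0)
    shares = np.array([0.30, 0.15, 0.12, 0.12, 0.10, 0.09, 0.06, 0.06])
    if len(taxa) != shares.size:
        shares = np.full(len(taxa), 1.0 / len(taxa))
    out = {}
    for taxon, share in zip(taxa, shares):
        log_dev = np.zeros_like(ages)
        for k in (1, 2, 3):
            amp = variability * rng.uniform(0.3, 1.0) / k
            phase = rng.uniform(0, 2 * np.pi)
            log_dev += amp * np.sin(2 * np.pi * k * (ages - ages.min()) / span + phase)
        out[taxon] = total_scale * share * np.exp(log_dev)
    return out


def gen_core(
    model: AgeDepthModel,
    trajectories: Mapping[str, np.ndarray],
    calib: CalibrationSet,
    layer_depths: np.ndarray,
    tracer_added: int = 20_000,
    volume: float = 0.625,
    expected_tracer_count: float = 300.0,
    fire_ages_calbp: Sequence[float] = (),
    charcoal_background: float = 8.0,
    charcoal_spike: float = 60.0,
    noise: bool = True,
    seed: int | None = None,
) -> tuple[list[LayerSample], SyntheticTruth]:
    """Generate layer samples whose expected counts invert the full
    analysis chain.

    For each layer the latent biomass B_i fixes the expected influx
    PAR_i = (B_i - intercept_i)/slope_i, hence the expected concentration
    C_i = PAR_i / S. The tallied tracer count is Poisson around
    ``expected_tracer_count`` and each taxon tally is Poisson with mean
    C_i * V * tracer_counted / tracer_added, conditioning on the realized
    tracer count (slide-level counting). Charcoal tallies are Poisson with
    a background mean plus a spike in layers whose age bin contains a fire.
    With ``noise=False`` every count equals its expectation, so the
    pipeline reconstructs B_i exactly.
    """
    layer_depths = np.asarray(layer_depths, dtype=float)
    n_layers = layer_depths.size
    for taxon, entry in calib.items():
        if taxon in trajectories and entry.slope <= 0:
            raise InputError(f"calibration slope for {taxon!r} must be > 0 to invert")
    rng = np.random.default_rng(seed)
    ages = np.array([age_at_depth(model, d) for d in layer_depths])
    rates = np.array([sedimentation_rate(model, d) for d in layer_depths])
    # age bin edges: midpoints between layers (fire spikes land in one bin)
    edges = np.concatenate([[ages[0] - (ages[1] - ages[0]) / 2],
                            (ages[:-1] + ages[1:]) / 2,
                            [ages[-1] + (ages[-1] - ages[-2]) / 2]]) \
        if n_layers > 1 else np.array([ages[0] - 25, ages[0] + 25])
    fire_layer = np.zeros(n_layers, dtype=bool)
    for fa in fire_ages_calbp:
        k = np.searchsorted(edges, fa) - 1
        if 0 <= k < n_layers:
            fire_layer[k] = True
    layers = []
    for j in range(n_layers):
        if noise:
            tracer_counted = float(rng.poisson(expected_tracer_count))
        else:
            tracer_counted = float(expected_tracer_count)
        counts = {}
        for taxon, traj in trajectories.items():
            entry = calib[taxon]
            par_true = max(traj[j] - entry.intercept, 0.0) / entry.slope
            conc_true = par_true / rates[j]
            lam = conc_true * volume * tracer_counted / tracer_added
            counts[taxon] = float(rng.poisson(lam)) if noise else lam
        char_mean = (charcoal_background + (charcoal_spike if fire_layer[j] else 0.0))
        char = float(rng.poisson(char_mean)) if noise else char_mean
        layers.append(LayerSample(
            depth=float(layer_depths[j]), volume=volume, taxon_counts=counts,
            tracer_counted=tracer_counted, tracer_added=tracer_added,
            charcoal_count=char, charcoal_volume=1.0,
        ))
    truth = SyntheticTruth(
        seed=seed,
        params=dict(tracer_added=tracer_added, volume=volume,
                    expected_tracer_count=expected_tracer_count,
                    charcoal_background=charcoal_background,
                    charcoal_spike=charcoal_spike, noise=noise),
        trajectories={t: np.asarray(v, dtype=float) for t, v in trajectories.items()},
        trajectory_ages=ages,
        fire_years=tuple(float(a) for a in fire_ages_calbp),
    )
    return layers, truth


def gen_fire_history(
    n_trees: int = 20,
    span: tuple[int, int] = (1500, 2000),
    mean_interval: float = 10.0,
    interval_shape: float = 2.0,
    recording_prob: float = 0.5,
    season_mix: Mapping[str, float] = DEFAULT_SEASON_MIX,
    span_jitter: float = 0.25,
    seed: int | None = None,
) -> tuple[FireScarDataset, SyntheticTruth]:
    """Latent fire years from a gamma renewal process, recorded imperfectly.

    Intervals between fires are gamma with mean ``mean_interval`` and shape
    ``interval_shape`` (shape 1 = memoryless). Each tree spans the record
    apart from random trims of up to ``span_jitter`` of the record at each
    end (0 = every tree spans the whole period), and independently records
    each fire within its span with probability ``recording_prob``; scar
    positions are drawn from ``season_mix``.
    """
    if mean_interval <= 0:
        raise InputError("mean_interval must be > 0")
    if not 0 < recording_prob <= 1:
        raise InputError("recording_prob must be in (0, 1]")
    rng = np.random.default_rng(seed)
    start, end = int(min(span)), int(max(span))
    # latent fire years: gamma renewal walk across the period
    scale = mean_interval / interval_shape
    t = start + rng.gamma(interval_shape, scale)
    fire_years: list[int] = []
    while t <= end:
        y = int(round(t))
        if not fire_years or y > fire_years[-1]:
            fire_years.append(y)
        t += rng.gamma(interval_shape, scale)
    positions = list(season_mix)
    probs = np.asarray([season_mix[p] for p in positions], dtype=float)
    probs = probs / probs.sum()
    trees = []
    length = end - start
    for i in range(n_trees):
        inner = start + int(rng.uniform(0, span_jitter * length)) if span_jitter else start
        outer = end - int(rng.uniform(0, span_jitter * length)) if span_jitter else end
        if outer <= inner:
            inner, outer = start, end
        scars = {}
        for y in fire_years:
            if inner <= y <= outer and rng.random() < recording_prob:
                scars[y] = positions[rng.choice(len(positions), p=probs)]
        trees.append(TreeRecord(tree_id=f"T{i + 1:03d}",
                                species=rng.choice(["PSME", "PILA", "PIPO", "CHLA"]),
                                inner_year=inner, outer_year=outer, scars=scars))
    truth = SyntheticTruth(
        seed=seed,
        params=dict(n_trees=n_trees, span=(start, end), mean_interval=mean_interval,
                    interval_shape=interval_shape, recording_prob=recording_prob,
                    span_jitter=span_jitter),
        fire_years=tuple(fire_years),
    )
    return FireScarDataset(trees=tuple(trees)), truth


def gen_pdsi(
    age_grid: np.ndarray | None = None,
    ar_coefficient: float = 0.7,
    marginal_sd: float = 2.0,
    anomaly_windows: Sequence[tuple[float, float, float]] = (
        (*MCA_WINDOW, -1.0),  # drier during the warm anomaly
        (*LIA_WINDOW, +1.0),  # wetter during the cool anomaly
    ),
    seed: int | None = None,
) -> tuple[ProxySeries, SyntheticTruth]:
    """Annual AR(1) drought-index series with stepwise anomaly shifts.

    ``age_grid`` is in calBP (default: annual, 2000 to -58 calBP).
    ``marginal_sd`` is the stationary SD of the AR(1) noise; each anomaly
    window (lo, hi, shift) adds *shift* PDSI units inside [lo, hi] calBP.
    With ``marginal_sd=0`` the output is the exact step function.
    """
    if not abs(ar_coefficient) < 1:
        raise InputError("|ar_coefficient| must be < 1")
    if age_grid is None:
        age_grid = np.arange(-58.0, 2000.0 + 1)
    ages = np.sort(np.asarray(age_grid, dtype=float))
    rng = np.random.default_rng(seed)
    n = ages.size
    noise = np.zeros(n)
    if marginal_sd > 0:
        innov_sd = marginal_sd * np.sqrt(1 - ar_coefficient ** 2)
        noise[0] = rng.normal(0, marginal_sd)
        e = rng.normal(0, innov_sd, size=n - 1)
        for i in range(1, n):
            noise[i] = ar_coefficient * noise[i - 1] + e[i - 1]
    shift = np.zeros(n)
    for lo, hi, s in anomaly_windows:
        shift[(ages >= min(lo, hi)) & (ages <= max(lo, hi))] += s
    truth = SyntheticTruth(
        seed=seed,
        params=dict(ar_coefficient=ar_coefficient, marginal_sd=marginal_sd),
        anomaly_windows=tuple(anomaly_windows),
    )
    return ProxySeries(ages=ages, values=noise + shift, label="PDSI"), truth


def gen_correlated_proxies(
    age_range: tuple[float, float] = (0.0, 2000.0),
    mean_spacing: float = 20.0,
    rho: float = 0.85,
    corr_window: tuple[float, float] = LIA_WINDOW,
    labels: tuple[str, str] = ("CHAR", "VRI"),
    seed: int | None = None,
) -> tuple[ProxySeries, ProxySeries, SyntheticTruth]:
    """Two irregularly sampled proxies correlated only inside one window.

    Sample ages have jittered ~``mean_spacing``-year gaps. Outside
    ``corr_window`` the two series are independent standard normals; inside
    it y = rho*x + sqrt(1-rho^2)*noise. Used to test that the rolling
    correlation localizes an embedded signal.
    """
    rng = np.random.default_rng(seed)
    lo, hi = min(age_range), max(age_range)
    gaps = rng.uniform(0.5 * mean_spacing, 1.5 * mean_spacing,
                       size=int(2 * (hi - lo) / mean_spacing))
    ages = lo + np.cumsum(gaps)
    ages = np.concatenate([[lo], ages[ages < hi]])
    n = ages.size
    x = rng.standard_normal(n)
    indep = rng.standard_normal(n)
    inside = (ages >= min(corr_window)) & (ages <= max(corr_window))
    y = np.where(inside, rho * x + np.sqrt(1 - rho ** 2) * indep, indep)
    truth = SyntheticTruth(seed=seed,
                           params=dict(rho=rho, mean_spacing=mean_spacing),
                           anomaly_windows=((*corr_window, rho),))
    return (ProxySeries(ages=ages, values=x, label=labels[0]),
            ProxySeries(ages=ages, values=y, label=labels[1]),
            truth)


@dataclass
class StudyBundle:
    """Everything one synthetic study produces, plus its latent truth."""

    model: AgeDepthModel
    layers: list
    calib: CalibrationSet
    pdsi: ProxySeries
    firescars: FireScarDataset
    truth_core: SyntheticTruth
    truth_chron: SyntheticTruth
    truth_pdsi: SyntheticTruth
    truth_fire: SyntheticTruth


def simulate_study(
    seed: int | None = None,
    n_layers: int = 60,
    noise: bool = True,
    tracer_added: int = 20_000,
) -> StudyBundle:
    """One full synthetic study at the default conditions: a 60-layer,
    ~2,900-year core with 8 taxa, an annual drought index, and a ~20-tree
    fire-scar collection over AD 1500-2000."""
    root = np.random.SeedSequence(seed)
    s_chron, s_traj, s_core, s_pdsi, s_fire = [
        int(s.generate_state(1)[0] % (2 ** 31)) for s in root.spawn(5)
    ]
    model, truth_chron = gen_age_depth(seed=s_chron)
    layer_depths = np.linspace(2.5, 297.5, n_layers)
    layer_ages = np.array([age_at_depth(model, d) for d in layer_depths])
    traj = gen_biomass_trajectories(layer_ages, seed=s_traj)
    calib = default_calibration()
    # charcoal fires: decadal-scale regime over the core span
    rng_fire = np.random.default_rng(s_core)
    fire_ages = np.sort(rng_fire.uniform(layer_ages.min(), layer_ages.max(), size=40))
    layers, truth_core = gen_core(
        model, traj, calib, layer_depths, tracer_added=tracer_added,
        fire_ages_calbp=fire_ages, noise=noise, seed=s_core,
    )
    pdsi, truth_pdsi = gen_pdsi(seed=s_pdsi)
    firescars, truth_fire = gen_fire_history(seed=s_fire)
    return StudyBundle(model=model, layers=layers, calib=calib, pdsi=pdsi,
                       firescars=firescars, truth_core=truth_core,
                       truth_chron=truth_chron, truth_pdsi=truth_pdsi,
                       truth_fire=truth_fire)


def write_study_inputs(bundle: StudyBundle, directory) -> dict[str, str]:
    """Write a study bundle as the input files the pipeline reads, plus a
    JSON record of the latent truth. Returns the path map (keys match
    :class:`~sedfire.pipeline.RunConfig` field names)."""
    import json
    from pathlib import Path

    from . import io as sfio

    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    paths = {
        "age_depth_path": str(directory / "age_depth.csv"),
        "pollen_path": str(directory / "pollen.csv"),
        "layers_path": str(directory / "layers.csv"),
        "calibration_path": str(directory / "calibration.csv"),
        "pdsi_path": str(directory / "pdsi.csv"),
        "fhx_path": str(directory / "firescars.fhx"),
    }
    sfio.write_age_depth_csv(bundle.model, paths["age_depth_path"])
    sfio.write_core_csv(bundle.layers, paths["pollen_path"], paths["layers_path"])
    sfio.write_calibration(bundle.calib, paths["calibration_path"])
    sfio.write_pdsi_csv(bundle.pdsi, paths["pdsi_path"])
    sfio.write_fhx(bundle.firescars, paths["fhx_path"])
    truth = {
        "core": {
            "trajectory_ages": bundle.truth_core.trajectory_ages.tolist(),
            "trajectories": {t: v.tolist()
                             for t, v in bundle.truth_core.trajectories.items()},
            "fire_ages_calbp": list(bundle.truth_core.fire_years),
            "params": bundle.truth_core.params,
        },
        "chronology": {
            "sedimentation_cm_per_yr": bundle.truth_chron.sedimentation.tolist(),
            "params": bundle.truth_chron.params,
        },
        "pdsi": {"anomaly_windows": [list(w) for w in bundle.truth_pdsi.anomaly_windows],
                 "params": bundle.truth_pdsi.params},
        "fire": {"fire_years_ad": list(bundle.truth_fire.fire_years),
                 "params": bundle.truth_fire.params},
    }
    truth_path = directory / "truth.json"
    with open(truth_path, "w", encoding="utf-8") as fh:
        json.dump(truth, fh, indent=2, default=str)
    paths["truth_path"] = str(truth_path)
    return paths
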