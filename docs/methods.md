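# Methods

This note documents the statistical model behind each pipeline stage, the
defaults and why they were chosen, what the synthetic generators do and do
not emulate, and the numerical conventions that matter for reproducing a
run.

## Chronology

The package consumes an externally produced age–depth table (depth cm,
age calBP) — typically the posterior median chronology of a Bayesian
Pb-210/C-14 model — and treats it as a piecewise-linear curve. Ages are in
calBP (present = AD 1950, negative after 1950); fire-scar data stay in
calendar AD, and the two conventions meet only through `calbp_to_ad`.

Deposition time (yr/cm) is the local slope of that curve; the
sedimentation rate is its reciprocal. Exactly at an interior control point
the slope is ambiguous, so the mean of the two flanking segment slopes is
used — a symmetric convention, configurable in effect by querying inside
either segment instead. Queries outside the dated range raise an error by
default; constant-rate extrapolation can be enabled explicitly
(`allow_extrapolation=True`) so a chronology is never extended silently.
Whether the table comes from a posterior mean or median chronology is the
caller's choice; the math downstream needs only ages and rates.

## Influx

Concentration uses the plain ratio estimator
`C = (count/tracer) · (spike/volume)`. No small-sample bias correction is
applied — the ratio is the standard estimator in exotic-marker palynology —
but a warning is emitted when fewer than 50 tracer spores were tallied,
where the estimator's noise becomes appreciable. A layer with *zero*
tracer spores counted is unmeasurable, not pollen-free: it propagates as a
flagged gap (NaN + mask) rather than a zero, and downstream stages skip it.
Charcoal needs no tracer; its sample volume defaults to 1 cm³ (contiguous
1-cm³ subsampling is the field convention) and is overridable per layer.

## Biomass calibration and uncertainty

Per-taxon biomass is linear in PAR. The calibration coefficients
(intercept, slope, SE of the regression estimate, per taxon) come from an
external vegetation-survey study and are read from a config file, never
hard-coded; the synthetic `default_calibration()` is labelled synthetic
and used only by the generators and tests.

Monte-Carlo propagation: per iteration, per taxon, an error
`ε ~ N(0, SE_taxon)` is added to the point prediction and the taxa summed;
over 10,000 iterations the mean and the SD of the iterate totals are
reported. Choices worth stating:

* Draws are independent across taxa — no between-taxon calibration
  covariance is published, and independence gives the quadrature SE
  `√(Σ SEᵢ²)` in closed form, which the tests verify.
* The reported SE is the SD of the iterate distribution (a predictive SE),
  not SD/√n_iter: the spread of the prediction is what error bars on a
  reconstruction should show.
* Negative point predictions (possible with a negative intercept at low
  PAR) are floored at 0 and the taxon flagged on the estimate; biomass is
  non-negative, and the flag preserves the information that flooring
  occurred.
* All SEs zero short-circuits to the exact deterministic sum with SE 0.
* Reproducibility: taxa are processed in sorted name order and each layer
  receives its own child seed (`SeedSequence.spawn`), so the same seed
  gives bit-identical output regardless of input ordering.

## Vegetation response index

`VRI = (tolerant − intolerant) / (tolerant + intolerant)` over raw counts
of the four formula taxa; scale invariance makes counts and percentages
equivalent. Taxon names resolve case-insensitively by prefix, so
subgeneric pollen types (e.g. "Pinus subg. Strobus") pool into their
formula taxon. A layer with a zero four-taxon sum is a flagged gap — 0/0
carries no canopy information. A formula taxon absent from an entire core
is treated as zero with a warning, since genuine absence and a missing
column are indistinguishable in count data.

## Rolling correlation

Proxies are brought to a common regular grid (default 20-year spacing, the
native resolution of the comparison) by a cubic smoothing spline: the
penalized natural-spline fit, with the penalty chosen by generalized
cross-validation when not supplied, and an interpolating cubic spline at
penalty 0. The grid never extends beyond the observed age range. Series
are standardized to z-scores over their full length, and PDSI and VRI are
multiplied by −1 so that dry, open-canopy and high-charcoal all point the
same way; correlations then carry the signs under which "fire-like"
behaviour is positive.

Windows default to 200 years (10 grid points) advancing in 20-year steps.
The window length is a free design choice — it must be at least the step
and long enough for a t test with n−2 df to be meaningful — and every
result records the window used. Per-window p-values are two-sided from the
t distribution; the Benjamini–Hochberg step-up adjustment (delegated to
statsmodels behind the `adjust_bh` surface) is applied across all windows
of a pair. BH controls the false-discovery rate across windows but does
not correct for serial correlation within windows, so an optional AR(1)
effective-sample-size correction
(`n_eff = n(1 − r₁ₓr₁ᵧ)/(1 + r₁ₓr₁ᵧ)`) is available; it is off by default
to keep the plain t-test convention, and the choice is recorded in the run
manifest. Significant runs are maximal stretches of consecutive windows
with adjusted p below alpha, reported with their mean r.

## Fire history

A tree is in recording status throughout its [inner, outer] span by
default; the stricter convention that recording starts at the first scar
("recorder rule") is selectable, since both are in active use and the
choice changes sample depth early in a record. The composite keeps years
with ≥ `min_trees` scarred trees *and* ≥ `min_depth` recording trees;
(2, 2) is the conventional single-tree-wound filter and (1, 1) the
unfiltered chronology. Return intervals are first differences of composite
fire years restricted to an inclusive period (the AD 1700–1900 window is
the usual maximum-sample-depth summary); the median uses the
mean-of-middle-two convention. Seasonality fractions are computed over
scars with a known intra-ring position; unknowns are tallied but excluded
from the denominator. Dormant-season scars are stored under the calendar
year assigned by the data provider — that assignment is a lab convention
this tool cannot recompute.

The FHX2 reader/writer supports the canonical dialect (header, vertical
ids, one row per year with `{`/`}` span markers, uppercase season letters
D/E/M/L/A/U, `|` recording, `.` non-recording); files written by the
package round-trip byte-identically.

## Synthetic generators

What they emulate: variable sedimentation (lognormal segment rates,
rescaled to a fixed span); smooth latent per-taxon biomass (log-scale
low-frequency sinusoids — millennial turnover, not annual noise); Poisson
counting at every tally (tracer, pollen conditional on the realized tracer
count, charcoal) — the simplest model consistent with the ratio estimator;
charcoal spikes added to the Poisson mean in layers whose age bin contains
a fire; an AR(1) drought index with stepwise anomaly shifts (drier in the
MCA-like window 1200–850 calBP, wetter in the LIA-like window 750–50
calBP); and a gamma-renewal fire process (shape 2 — mildly regular
intervals; shape 1 recovers the memoryless case) recorded by each living
tree independently with a fixed probability, with scar seasons drawn from
a mix dominated by latewood and dormant positions.

What they do not emulate: taphonomy (sediment mixing, focusing,
differential preservation), pollen-dispersal physics and source-area
effects, spatially explicit fire spread, crossdating error, and
calibration-coefficient error in the *generator* (latent truth is exact by
construction). Passing recovery tests therefore demonstrates the
correctness of the estimators under the stated counting model, not the
field accuracy of any real-core reconstruction.

Default conditions (used by the tests and the acceptance script): 60
layers at 5-cm increments over a 300-cm, ~2,900-year core (≈50-year
resolution); 8 taxa totalling ~130 Mg/ha; 0.625-cm³ pollen samples spiked
with 20,000 tracer spores and ~300 spores tallied per slide; per-taxon
calibration SEs of 4–7 Mg/ha (so calibration error dominates counting
error, as in a realistic application); 10,000 MC iterations; fire regime
with a 10-year mean interval recorded by 20 trees over AD 1500–2000 at
recording probability 0.5.

## Numerical conventions and edge cases

* Percentiles (medians, IQRs) use linear interpolation (numpy default).
* Baseline and period bounds are inclusive on both ends.
* The embedded-signal analysis in the acceptance surface resamples the
  generated proxies with penalty 0 (interpolation): GCV on short,
  white-noise-dominated series can select heavy smoothing and flatten the
  very signal under test, and the generated proxies are already at
  ~20-year spacing. Real applications with denser, noisier series should
  prefer GCV.
* Problem sizes in the acceptance script (20 seeded studies for coverage,
  50 replicates for detection, 200 random datasets for the composite
  oracle) are the package's chosen desk-scale study sizes; all complete in
  seconds.
* Same config + same seed reproduces every output byte-identically; the
  run manifest stores input SHA-256 hashes, the seed and all settings.

## Known limitations

* The rolling-correlation stage assumes the spline-resampled series are a
  fair representation of the underlying processes; very uneven sampling
  relative to the grid step will alias.
* The AR(1) significance correction is approximate (effective-n plug-in),
  not an exact autocorrelation-aware test.
* FHX2 support targets the canonical dialect; exotic header variants from
  legacy software may need conversion.
* No spatial structure: sites are independent, and no pollen source-area
  model links PAR to stand-scale biomass beyond the linear calibration.
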