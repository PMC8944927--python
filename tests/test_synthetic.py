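import numpy as np
import pytest

from sedfire.biomass import biomass_series
from sedfire.chronology import age_at_depth, sedimentation_rate
from sedfire.firehistory import composite, median_fri, seasonality_summary
from sedfire.influx import influx_series
from sedfire.synthetic import (DEFAULT_TAXA, default_calibration, gen_age_depth,
                               gen_biomass_trajectories, gen_core,
                               gen_correlated_proxies, gen_fire_history,
                               gen_pdsi, simulate_study)


class TestGenAgeDepth:
    def test_zero_variability_is_exactly_linear(self):
        model, _ = gen_age_depth(n_controls=8, total_depth=200, age_span=2000,
                                 rate_variability=0.0, seed=0, age_top=0.0)
        slopes = np.diff(model.ages) / np.diff(model.depths)
        np.testing.assert_allclose(slopes, slopes[0])
        assert model.ages[-1] - model.ages[0] == pytest.approx(2000.0)

    def test_seeded_determinism(self):
        a, _ = gen_age_depth(seed=42)
        b, _ = gen_age_depth(seed=42)
        np.testing.assert_array_equal(a.ages, b.ages)

    def test_derived_rates_match_truth_profile(self):
        model, truth = gen_age_depth(n_controls=6, seed=3)
        mids = (model.depths[:-1] + model.depths[1:]) / 2
        rates = [sedimentation_rate(model, d) for d in mids]
        np.testing.assert_allclose(rates, truth.sedimentation, rtol=1e-10)


class TestGenCore:
    def _setup(self, seed=0, n_layers=15):
        model, _ = gen_age_depth(seed=seed)
        depths = np.linspace(5, 295, n_layers)
        ages = np.array([age_at_depth(model, d) for d in depths])
        traj = gen_biomass_trajectories(ages, seed=seed)
        return model, depths, traj, default_calibration()

    def test_noise_free_round_trip_is_exact(self):
        model, depths, traj, calib = self._setup()
        # noise off everywhere: expected counts and zero calibration error
        for t in calib:
            calib[t] = type(calib[t])(calib[t].intercept, calib[t].slope, 0.0)
        layers, truth = gen_core(model, traj, calib, depths, noise=False, seed=0)
        inf = {t: influx_series(layers, model, t) for t in DEFAULT_TAXA}
        est = biomass_series(inf, calib, n_iter=1, seed=0)
        truth_total = sum(truth.trajectories[t] for t in DEFAULT_TAXA)
        recon = np.array([e.mean_total for e in est])
        np.testing.assert_allclose(recon, truth_total, rtol=1e-9)

    def test_rmse_halves_when_expected_counts_quadruple(self):
        # sqrt(n) counting statistics: 4x the tracer tally and spike halve
        # the per-layer reconstruction RMSE (seeded replicate average)
        errs = {}
        for scale in (1.0, 4.0):
            sq = []
            for rep in range(6):
                model, depths, traj, calib = self._setup(seed=rep, n_layers=25)
                calib0 = default_calibration()
                for t in calib0:  # isolate counting noise
                    calib0[t] = type(calib0[t])(calib0[t].intercept,
                                                calib0[t].slope, 0.0)
                layers, truth = gen_core(
                    model, traj, calib0, depths, seed=1000 + rep,
                    expected_tracer_count=150 * scale,
                    tracer_added=20_000)
                inf = {t: influx_series(layers, model, t) for t in DEFAULT_TAXA}
                est = biomass_series(inf, calib0, n_iter=1, seed=0)
                truth_total = sum(truth.trajectories[t] for t in DEFAULT_TAXA)
                recon = np.array([e.mean_total for e in est])
                sq.extend((recon - truth_total) ** 2)
            errs[scale] = np.sqrt(np.mean(sq))
        assert errs[4.0] == pytest.approx(errs[1.0] / 2, rel=0.35)

    def test_zero_biomass_taxon_gives_zero_expected_count(self):
        model, depths, traj, calib = self._setup(n_layers=5)
        traj["Pinus"] = np.zeros_like(traj["Pinus"])
        layers, _ = gen_core(model, traj, calib, depths, noise=False, seed=0)
        assert all(s.taxon_counts["Pinus"] == 0.0 for s in layers)

    def test_fire_layers_get_charcoal_spikes(self):
        model, depths, traj, calib = self._setup(n_layers=30)
        ages = np.array([age_at_depth(model, d) for d in depths])
        fire_ages = [float(ages[10])]
        layers, _ = gen_core(model, traj, calib, depths, noise=False,
                             fire_ages_calbp=fire_ages,
                             charcoal_background=5.0, charcoal_spike=50.0, seed=0)
        counts = np.array([s.charcoal_count for s in layers])
        assert counts[10] == pytest.approx(55.0)
        assert np.all(np.delete(counts, 10) == 5.0)


class TestGenFireHistory:
    def test_perfect_recording_recovers_true_fire_years(self):
        ds, truth = gen_fire_history(n_trees=5, recording_prob=1.0,
                                     span_jitter=0.0, seed=0)
        comp = composite(ds, min_trees=2, min_depth=2)
        assert comp.fire_years == truth.fire_years

    def test_median_fri_approaches_true_interval(self):
        # 20 trees over a 500-y record: composite median FRI within 20% of
        # the renewal process's mean interval, averaged over seeds
        fris = []
        for seed in range(8):
            ds, _ = gen_fire_history(n_trees=20, span=(1400, 1900),
                                     mean_interval=12.0, recording_prob=0.6,
                                     seed=seed)
            fri = median_fri(composite(ds, 2, 2))
            if fri is not None:
                fris.append(fri)
        # gamma(shape 2) median is ~0.84 of the mean
        assert np.mean(fris) == pytest.approx(0.84 * 12.0, rel=0.2)

    def test_pure_latewood_mix(self):
        ds, _ = gen_fire_history(n_trees=6, season_mix={"latewood": 1.0}, seed=1)
        assert seasonality_summary(ds)["latewood_dormant_fraction"] == 1.0

    def test_seeded_determinism(self):
        a, ta = gen_fire_history(seed=9)
        b, tb = gen_fire_history(seed=9)
        assert ta.fire_years == tb.fire_years
        assert [t.scars for t in a.trees] == [t.scars for t in b.trees]


class TestGenPdsi:
    def test_zero_noise_exact_step_function(self):
        grid = np.arange(0.0, 1500.0)
        s, _ = gen_pdsi(age_grid=grid, marginal_sd=0.0,
                        anomaly_windows=[(400.0, 800.0, -1.5)], seed=0)
        inside = (s.ages >= 400) & (s.ages <= 800)
        assert np.all(s.values[inside] == -1.5)
        assert np.all(s.values[~inside] == 0.0)

    def test_anomaly_shift_detectable(self):
        s, _ = gen_pdsi(ar_coefficient=0.5, marginal_sd=1.0,
                        anomaly_windows=[(500.0, 1000.0, 2.0)], seed=4)
        inside = (s.ages >= 500) & (s.ages <= 1000)
        diff = s.values[inside].mean() - s.values[~inside].mean()
        se = np.sqrt(s.values[inside].var() / inside.sum()
                     + s.values[~inside].var() / (~inside).sum())
        # AR(1) inflates the naive SE ~sqrt((1+phi)/(1-phi)) ~ 1.73 here
        assert abs(diff - 2.0) < 3 * 1.8 * se

    def test_white_noise_limit_uncorrelated(self):
        s, _ = gen_pdsi(ar_coefficient=0.0, marginal_sd=1.0,
                        anomaly_windows=(), seed=5)
        v = s.values - s.values.mean()
        rho1 = (v[:-1] @ v[1:]) / (v @ v)
        assert abs(rho1) < 3 / np.sqrt(v.size)

    def test_ar_coefficient_bounds(self):
        with pytest.raises(Exception):
            gen_pdsi(ar_coefficient=1.0)


class TestGenCorrelatedProxies:
    def test_correlation_confined_to_window(self):
        x, y, _ = gen_correlated_proxies(rho=0.9, seed=6)
        inside = (x.ages >= 50) & (x.ages <= 750)
        r_in = np.corrcoef(x.values[inside], y.values[inside])[0, 1]
        r_out = np.corrcoef(x.values[~inside], y.values[~inside])[0, 1]
        assert r_in > 0.7
        assert abs(r_out) < 0.3

    def test_strictly_increasing_irregular_ages(self):
        x, _, _ = gen_correlated_proxies(seed=7)
        assert np.all(np.diff(x.ages) > 0)
        assert np.diff(x.ages).std() > 0  # genuinely irregular


class TestStudyBundle:
    def test_reproducible_from_seed(self):
        a = simulate_study(seed=5, n_layers=10)
        b = simulate_study(seed=5, n_layers=10)
        assert [s.taxon_counts for s in a.layers] == [s.taxon_counts for s in b.layers]
        np.testing.assert_array_equal(a.pdsi.values, b.pdsi.values)
        assert a.truth_fire.fire_years == b.truth_fire.fire_years
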