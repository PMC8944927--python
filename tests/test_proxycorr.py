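import numpy as np
import pytest
from scipy import stats

from conftest import brute_pearson
from sedfire.errors import InputError
from sedfire.proxycorr import (ProxySeries, adjust_bh, orient,
                               rolling_correlation, significant_windows,
                               spline_resample, standardize)


def series(values, ages=None, label="other"):
    values = np.asarray(values, float)
    ages = np.arange(values.size, dtype=float) if ages is None else np.asarray(ages, float)
    return ProxySeries(ages=ages, values=values, label=label)


class TestStandardize:
    def test_mean_zero_sd_one(self):
        z = standardize(series([3.0, 1.0, 4.0, 1.0, 5.0]))
        assert abs(z.values.mean()) < 1e-12
        assert z.values.std(ddof=1) == pytest.approx(1.0)

    def test_affine_invariance(self):
        x = series([3.0, 1.0, 4.0, 1.0, 5.0])
        y = series(7.0 * x.values - 2.0)
        np.testing.assert_allclose(standardize(x).values, standardize(y).values,
                                   atol=1e-12)

    def test_hand_zscores(self):
        vals = np.array([2.0, 4.0, 6.0, 8.0, 10.0])  # mean 6, sd(ddof=1) sqrt(10)
        z = standardize(series(vals))
        np.testing.assert_allclose(z.values, (vals - 6.0) / np.sqrt(10.0))

    def test_zero_variance_rejected(self):
        with pytest.raises(InputError):
            standardize(series([5.0, 5.0, 5.0]))


class TestOrient:
    def test_involution(self):
        x = series([1.0, -2.0, 3.0])
        np.testing.assert_array_equal(orient(orient(x, True), True).values, x.values)

    def test_no_flip_identity(self):
        x = series([1.0, -2.0, 3.0])
        assert orient(x, False) is x

    def test_flip_negates_correlation(self):
        rng = np.random.default_rng(0)
        x = series(rng.standard_normal(40))
        y = series(rng.standard_normal(40))
        r0 = brute_pearson(x.values, y.values)
        r1 = brute_pearson(x.values, orient(y, True).values)
        assert r1 == pytest.approx(-r0)


class TestSplineResample:
    def test_interpolation_limit_on_grid_data(self):
        ages = np.arange(0.0, 400.0, 20.0)
        vals = np.sin(ages / 60.0)
        out = spline_resample(series(vals, ages), step=20.0, smoothing=0.0)
        np.testing.assert_allclose(out.ages, ages)
        np.testing.assert_allclose(out.values, vals, atol=1e-8)

    def test_cubic_polynomial_reproduction(self):
        ages = np.sort(np.random.default_rng(1).uniform(0, 1000, 40))
        vals = 1e-6 * ages**3 - 2e-4 * ages**2 + 0.1 * ages - 3
        out = spline_resample(series(vals, ages), step=20.0, smoothing=0.0)
        expect = 1e-6 * out.ages**3 - 2e-4 * out.ages**2 + 0.1 * out.ages - 3
        np.testing.assert_allclose(out.values, expect, atol=1e-6)

    def test_constant_series_stays_constant(self):
        ages = np.array([0.0, 15.0, 42.0, 77.0, 103.0, 160.0])
        out = spline_resample(series(np.full(6, 3.5), ages), step=20.0)
        np.testing.assert_allclose(out.values, 3.5, atol=1e-8)

    def test_grid_inside_observed_range(self):
        ages = np.array([7.0, 30.0, 55.0, 81.0, 120.0])
        out = spline_resample(series(np.arange(5.0), ages), step=20.0)
        assert out.ages[0] >= ages[0] and out.ages[-1] <= ages[-1]

    def test_too_few_points_rejected(self):
        with pytest.raises(InputError):
            spline_resample(series([1.0, 2.0, 3.0], [0.0, 20.0, 40.0]))


class TestRollingCorrelation:
    def _pair(self, n=60, seed=0):
        rng = np.random.default_rng(seed)
        ages = np.arange(n) * 20.0
        x = series(rng.standard_normal(n), ages, label="CHAR")
        y = series(rng.standard_normal(n), ages, label="PDSI")
        return x, y

    def test_identical_series_r_one(self):
        x, _ = self._pair()
        res = rolling_correlation(x, x, window=200.0, step=20.0)
        np.testing.assert_allclose(res.r, 1.0)

    def test_negated_series_r_minus_one(self):
        x, _ = self._pair()
        res = rolling_correlation(x, orient(x, True), window=200.0, step=20.0)
        np.testing.assert_allclose(res.r, -1.0)

    def test_matches_bruteforce_windowed_pearson(self):
        x, y = self._pair(seed=5)
        res = rolling_correlation(x, y, window=200.0, step=20.0)
        n_pts = 10
        for i, (r, p) in enumerate(zip(res.r, res.p)):
            sl = slice(i, i + n_pts)
            assert r == pytest.approx(brute_pearson(x.values[sl], y.values[sl]),
                                      abs=1e-12)
            t = r * np.sqrt((n_pts - 2) / (1 - r * r))
            assert p == pytest.approx(2 * stats.t.sf(abs(t), df=n_pts - 2),
                                      rel=1e-9)

    def test_full_record_window_reduces_to_global_pearson(self):
        x, y = self._pair(seed=9)
        res = rolling_correlation(x, y, window=20.0 * x.ages.size, step=20.0)
        assert res.r.size == 1
        assert res.r[0] == pytest.approx(brute_pearson(x.values, y.values),
                                         abs=1e-12)

    def test_affine_rescaling_invariance(self):
        x, y = self._pair(seed=2)
        x2 = series(3.0 * x.values + 1.0, x.ages, label="CHAR")
        y2 = series(-0.5 * y.values + 4.0, y.ages, label="PDSI")
        a = rolling_correlation(x, y, window=200.0)
        b = rolling_correlation(x2, y2, window=200.0)
        np.testing.assert_allclose(np.abs(a.r), np.abs(b.r), atol=1e-12)
        np.testing.assert_allclose(a.r, -b.r, atol=1e-12)  # one negative scale

    def test_mismatched_grids_rejected(self):
        x, y = self._pair()
        y_bad = series(y.values[:-1], y.ages[:-1] + 1.0, label="PDSI")
        with pytest.raises(InputError):
            rolling_correlation(x, y_bad)

    def test_ar1_correction_never_more_significant(self):
        rng = np.random.default_rng(4)
        n = 80
        ages = np.arange(n) * 20.0
        # strongly autocorrelated pair
        v = np.cumsum(rng.standard_normal(n))
        w = np.cumsum(rng.standard_normal(n))
        x = series(v, ages, label="CHAR")
        y = series(w, ages, label="PDSI")
        plain = rolling_correlation(x, y, window=200.0)
        adj = rolling_correlation(x, y, window=200.0, ar1_correction=True)
        # where both windows are positively autocorrelated, shrinking the
        # effective sample size can only weaken significance
        from sedfire.proxycorr import _ar1
        for i in range(plain.p.size):
            sl = slice(i, i + 10)
            if _ar1(x.values[sl]) > 0 and _ar1(y.values[sl]) > 0:
                assert adj.p[i] >= plain.p[i] - 1e-12


class TestAdjustBH:
    def test_hand_computed_stepup(self):
        np.testing.assert_allclose(adjust_bh(np.array([0.01, 0.02, 0.03])),
                                   [0.03, 0.03, 0.03])

    def test_single_p_unchanged(self):
        np.testing.assert_allclose(adjust_bh(np.array([0.2])), [0.2])

    def test_ties_unchanged(self):
        np.testing.assert_allclose(adjust_bh(np.full(5, 0.04)), np.full(5, 0.04))

    def test_known_mixed_vector(self):
        # hand step-up: sorted p (0.005,0.01,0.03,0.04,0.8), m=5
        # adj = min over j>=i of p_j*m/j -> (0.025, 0.025, 0.05, 0.05, 0.8)
        p = np.array([0.04, 0.005, 0.8, 0.01, 0.03])
        np.testing.assert_allclose(adjust_bh(p), [0.05, 0.025, 0.8, 0.025, 0.05])

    def test_adjusted_at_least_raw_and_capped(self):
        rng = np.random.default_rng(8)
        p = rng.uniform(size=50)
        adj = adjust_bh(p)
        assert np.all(adj >= p - 1e-15) and np.all(adj <= 1.0)

    def test_out_of_range_rejected(self):
        with pytest.raises(InputError):
            adjust_bh(np.array([0.5, 1.2]))


class TestSignificantWindows:
    def _result(self, p_adj, r=None):
        from sedfire.proxycorr import RollingCorrelationResult
        p_adj = np.asarray(p_adj, float)
        n = p_adj.size
        return RollingCorrelationResult(
            pair="X-Y", centers=np.arange(n) * 20.0,
            r=np.ones(n) * 0.5 if r is None else np.asarray(r, float),
            p=p_adj, p_adj=p_adj, window=200.0, step=20.0)

    def test_none_significant(self):
        assert significant_windows(self._result([0.5, 0.9, 0.06])) == []

    def test_all_significant_single_run(self):
        runs = significant_windows(self._result([0.01] * 5))
        assert len(runs) == 1 and runs[0]["n_windows"] == 5

    def test_runs_split_and_mean_r(self):
        runs = significant_windows(
            self._result([0.01, 0.01, 0.9, 0.02], r=[0.6, 0.8, 0.0, -0.5]))
        assert len(runs) == 2
        assert runs[0]["mean_r"] == pytest.approx(0.7)
        assert runs[1]["start_calbp"] == 60.0
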