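import numpy as np
import pytest

from seastress import thresholds as th
from seastress.gridio import MONTH_EDGES, MONTH_MIDPOINTS, monthly_archive

from conftest import make_daily


def _sinusoid_noise(years=40, amplitude=2.0, sd=0.5, seed=0, mean=15.0,
                    sd_by_doy=None):
    """Stationary single-cell daily series: sinusoid + white noise."""
    rng = np.random.default_rng(seed)
    n = years * 365
    doy = np.tile(np.arange(1, 366), years)
    sd_arr = sd if sd_by_doy is None else sd_by_doy[doy - 1]
    v = mean + amplitude * np.cos(2 * np.pi * (doy - 196) / 365.0) \
        + rng.normal(0.0, 1.0, n) * sd_arr
    return make_daily(v, years=(1975, 1975 + years - 1))


def _monthly_shares(mask_ds):
    m = mask_ds["mask"].values[:, 0, 0]
    doy = mask_ds["doy"].values
    month_of_doy = np.searchsorted(MONTH_EDGES[1:], doy - 1, side="right") + 1
    months = month_of_doy
    return np.array([(m & (months == k)).sum() for k in range(1, 13)])


class TestPercentile:
    def test_linear_interpolation_between_order_statistics(self):
        # brute force: with values 1..100 the 95th percentile interpolates
        # between the 95th and 96th order statistics at fraction 0.05
        assert th.percentile(np.arange(1, 101), 95) == pytest.approx(95.05)

    def test_constant_series(self):
        assert th.percentile(np.full(50, 7.0), 31.4) == 7.0

    def test_p100_is_maximum_and_p50_median(self):
        v = np.random.default_rng(0).normal(size=101)
        assert th.percentile(v, 100) == v.max()
        assert th.percentile(v, 50) == np.median(v)

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            th.percentile([], 50)


class TestFixedSC:
    def test_constant_field_yields_zero_exceedance(self):
        da = make_daily(np.full(365 * 3, 5.0), years=(2000, 2002))
        thr = th.fit_fixed_sc(da, (2000, 2002))
        assert thr.values[0, 0] == 5.0
        mask = th.count_extremes(da, thr)
        assert mask["percent"].values[0, 0] == 0.0

    def test_shift_equivariance(self):
        da = _sinusoid_noise()
        thr = th.fit_fixed_sc(da, (1975, 2014))
        thr2 = th.fit_fixed_sc(da + 3.5, (1975, 2014))
        np.testing.assert_allclose(thr2.values, thr.values + 3.5, atol=1e-10)

    def test_scale_equivariance(self):
        da = _sinusoid_noise()
        thr = th.fit_fixed_sc(da, (1975, 2014))
        thr2 = th.fit_fixed_sc(da * 2.0, (1975, 2014))
        np.testing.assert_allclose(thr2.values, thr.values * 2.0, atol=1e-10)

    def test_missing_reference_years_rejected(self):
        da = _sinusoid_noise(years=10)
        with pytest.raises(ValueError, match="missing reference years"):
            th.fit_fixed_sc(da, (1975, 2014))


class TestFixedSV:
    def test_constant_field_gives_flat_threshold(self):
        da = make_daily(np.full(365 * 3, 5.0), years=(2000, 2002))
        for fit in (th.fit_fixed_sv_binned, th.fit_fixed_sv_anomaly):
            thr = fit(da, (2000, 2002))
            np.testing.assert_allclose(thr.values, 5.0, atol=1e-10)

    def test_bin_size_must_divide_year(self):
        da = _sinusoid_noise(years=2)
        with pytest.raises(ValueError):
            th.fit_fixed_sv_binned(da, (1975, 1976), bin_days=7)

    def test_binned_threshold_tracks_pure_sinusoid(self):
        # no noise: the SV threshold must follow the seasonal cycle within
        # the 5-day bin span plus Gaussian-smoothing attenuation
        da = _sinusoid_noise(years=4, amplitude=2.0, sd=0.0)
        thr = th.fit_fixed_sv_binned(da, (1975, 1978))
        doy = np.arange(1, 366)
        cyc = 15.0 + 2.0 * np.cos(2 * np.pi * (doy - 196) / 365.0)
        assert np.max(np.abs(thr.values[:, 0, 0] - cyc)) < 0.25

    def test_sv_anomaly_equals_sc_without_seasonality(self):
        da = _sinusoid_noise(amplitude=0.0, sd=1.0)
        sc = th.fit_fixed_sc(da, (1975, 2014)).values[0, 0]
        sv = th.fit_fixed_sv_anomaly(da, (1975, 2014)).values[:, 0, 0]
        assert np.max(np.abs(sv - sc)) < 0.15

    def test_homoscedastic_binned_and_anomaly_counts_agree(self):
        da = _sinusoid_noise()
        n1 = th.count_extremes(da, th.fit_fixed_sv_binned(da, (1975, 2014)))
        n2 = th.count_extremes(da, th.fit_fixed_sv_anomaly(da, (1975, 2014)))
        c1 = n1["mask"].values.sum()
        c2 = n2["mask"].values.sum()
        assert abs(c1 - c2) / c2 < 0.10

    def test_seasonal_variance_contrast_between_sv_definitions(self):
        # noise sd doubled (variance x4) in winter: the binned variant keeps
        # monthly extreme shares roughly even; the anomaly variant piles
        # extremes into the high-variance winter half
        doy = np.arange(1, 366)
        winter = np.cos(2 * np.pi * (doy - 15) / 365.0) > 0
        sd_by_doy = np.where(winter, 1.0, 0.5)
        da = _sinusoid_noise(sd_by_doy=sd_by_doy, seed=4)
        shares_b = _monthly_shares(
            th.count_extremes(da, th.fit_fixed_sv_binned(da, (1975, 2014))))
        shares_a = _monthly_shares(
            th.count_extremes(da, th.fit_fixed_sv_anomaly(da, (1975, 2014))))
        winter_months = [12, 1, 2, 11]
        summer_months = [5, 6, 7, 8]
        w_a = shares_a[[m - 1 for m in winter_months]].sum()
        s_a = shares_a[[m - 1 for m in summer_months]].sum()
        w_b = shares_b[[m - 1 for m in winter_months]].sum()
        s_b = shares_b[[m - 1 for m in summer_months]].sum()
        assert w_a > 2.0 * s_a          # anomaly variant concentrates in winter
        assert w_b < 2.0 * s_b          # binned variant roughly equalizes


class TestCountExtremes:
    def test_all_below_upper_threshold_gives_zero(self):
        da = make_daily(np.zeros(365))
        thr = th.fit_fixed_sc(da, (2000, 2000)) + 1.0
        thr.attrs.update(tail="upper", variable="sst")
        assert th.count_extremes(da, thr)["percent"].values[0, 0] == 0.0

    def test_negation_symmetry(self):
        da = _sinusoid_noise(years=5)
        thr = th.fit_fixed_sc(da, (1975, 1979))
        up = th.count_extremes(da, thr)
        flipped = -da
        flipped.attrs["tail"] = "lower"
        flipped.name = "sst"
        nthr = -thr
        nthr.attrs.update(tail="lower", variable="sst")
        down = th.count_extremes(flipped, nthr)
        np.testing.assert_array_equal(up["mask"].values, down["mask"].values)

    def test_variable_mismatch_rejected(self):
        da = _sinusoid_noise(years=2)
        thr = th.fit_fixed_sc(da, (1975, 1976))
        thr.attrs["variable"] = "omega"
        with pytest.raises(ValueError, match="applied to"):
            th.count_extremes(da, thr)


class TestAMM:
    def _archive(self, values, years):
        return monthly_archive(values, years, [0.0], [0.0], "sst")

    def test_constant_archive(self):
        years = np.arange(2000, 2010)
        arch = self._archive(np.full((120, 1, 1), 4.0), years)
        amm = th.amm_series(arch, "max")
        assert np.all(amm.values == 4.0)

    def test_trend_slope_recovered(self):
        years = np.arange(1950, 2050)
        t = np.repeat(years, 12).astype(float)
        vals = (0.1 * (t - 2000))[:, None, None] + np.tile(
            np.cos(2 * np.pi * np.arange(12) / 12), 100)[:, None, None]
        arch = self._archive(vals, years)
        amm = th.amm_series(arch, "max").values[:, 0, 0]
        slope = np.polyfit(years, amm, 1)[0]
        assert slope == pytest.approx(0.1, abs=1e-3)

    def test_adaptive_sc_stationary_matches_long_run_mean(self):
        rng = np.random.default_rng(0)
        years = np.arange(1900, 2010)
        vals = rng.normal(0, 1, (len(years) * 12, 1, 1))
        arch = self._archive(vals, years)
        amm = th.amm_series(arch, "max").values[:, 0, 0]
        thr1 = th.adaptive_sc_threshold(arch, 2005, 100).values[0, 0]
        thr2 = th.adaptive_sc_threshold(arch, 2009, 100).values[0, 0]
        assert thr1 == pytest.approx(amm.mean(), abs=3 * amm.std() / 10)
        assert abs(thr1 - thr2) < 0.5 * amm.std()

    def test_adaptive_sc_lags_linear_trend_by_closed_form(self):
        # mean of the N preceding terms of an arithmetic sequence lags the
        # current term by m*(N+1)/2
        m = 0.02
        years = np.arange(1850, 2051)
        t = np.repeat(years, 12).astype(float)
        vals = (m * t)[:, None, None] + np.tile(
            np.cos(2 * np.pi * np.arange(12) / 12), len(years))[:, None, None]
        arch = self._archive(vals, years)
        amm_now = th.amm_series(arch, "max").sel(year=2050).values[0, 0]
        for n in (50, 100):
            thr = th.adaptive_sc_threshold(arch, 2050, n).values[0, 0]
            assert amm_now - thr == pytest.approx(m * (n + 1) / 2, rel=1e-6)
        # shorter window under positive trend -> strictly higher threshold
        assert (th.adaptive_sc_threshold(arch, 2050, 50).values[0, 0]
                > th.adaptive_sc_threshold(arch, 2050, 100).values[0, 0])

    def test_insufficient_archive_raises(self):
        arch = self._archive(np.zeros((120, 1, 1)), np.arange(2000, 2010))
        with pytest.raises(ValueError, match="window"):
            th.adaptive_sc_threshold(arch, 2009, 100)

    def test_per_year_thresholds_match_single_year(self):
        rng = np.random.default_rng(3)
        years = np.arange(1850, 2020)
        arch = self._archive(rng.normal(size=(len(years) * 12, 1, 1)), years)
        multi = th.adaptive_sc_thresholds(arch, np.arange(2000, 2010), 100)
        single = th.adaptive_sc_threshold(arch, 2005, 100)
        np.testing.assert_allclose(
            multi.sel(year=2005).values, single.values, atol=1e-12)


class TestAdaptiveSV:
    def _setup(self, delta_months=None):
        rng = np.random.default_rng(1)
        daily = _sinusoid_noise(years=40, seed=2)
        hist_sv = th.fit_fixed_sv_anomaly(daily, (1975, 2014))
        years = np.arange(1850, 2015)
        t = np.repeat(years, 12)
        base = np.tile(np.cos(2 * np.pi * np.arange(12) / 12), len(years))
        vals = (base + rng.normal(0, 0.1, len(t)))[:, None, None]
        arch = monthly_archive(vals, years, [0.0], [0.0], "sst")
        return hist_sv, arch

    def test_identity_window_leaves_threshold_unchanged(self):
        hist_sv, arch = self._setup()
        # rolling window == historical window => delta == 0
        thr = th.adaptive_sv_threshold(hist_sv, arch, (1915, 2014), 2015, 100)
        np.testing.assert_allclose(thr.values, hist_sv.values, atol=1e-10)

    def test_uniform_shift_moves_threshold_by_delta(self):
        # warming the rolling window (disjoint from the historical
        # reference) by delta in every month lifts the whole threshold by
        # exactly delta
        hist_sv, arch = self._setup()
        hist_years = (1850, 1949)
        window = np.isin(arch["year"].values, np.arange(1965, 2015))
        shifted_vals = arch.values.copy()
        shifted_vals[window] += 0.7
        shifted = arch.copy(data=shifted_vals)
        thr = th.adaptive_sv_threshold(hist_sv, shifted, hist_years, 2015, 50)
        base = th.adaptive_sv_threshold(hist_sv, arch, hist_years, 2015, 50)
        np.testing.assert_allclose(thr.values, base.values + 0.7, atol=1e-8)

    def test_month_interpolation_matches_independent_linear_oracle(self):
        rng = np.random.default_rng(4)
        delta = rng.normal(size=(12, 1, 1))
        interp = th.interp_month_to_doy(delta)[:, 0, 0]
        mids = MONTH_MIDPOINTS
        # independent oracle: periodic piecewise-linear through the month
        # midpoints, sampled at integer days
        x = np.concatenate([[mids[-1] - 365.0], mids, [mids[0] + 365.0]])
        y = np.concatenate([delta[-1:, 0, 0], delta[:, 0, 0], delta[:1, 0, 0]])
        expected = np.interp(np.arange(1.0, 366.0), x, y)
        np.testing.assert_allclose(interp, expected, atol=1e-12)

    def test_month_interpolation_single_month_pulse(self):
        delta = np.zeros((12, 1, 1))
        delta[0] = 1.0  # January-only change
        interp = th.interp_month_to_doy(delta)[:, 0, 0]
        mids = MONTH_MIDPOINTS
        # integer-day anchor (January midpoint, day 16) is hit exactly
        assert interp[int(mids[0]) - 1] == pytest.approx(1.0, abs=1e-12)
        assert interp.argmax() + 1 == pytest.approx(mids[0], abs=1)
        # flat zero between the February and December midpoints
        assert np.all(interp[int(np.ceil(mids[1])):int(mids[-1]) - 1] == 0.0)
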