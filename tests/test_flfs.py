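import numpy as np
import pytest

from ttmkit import flfs
from ttmkit.flfs import (
    CorrelationCurve,
    PhotonTimeList,
    channel_selection,
    circular_model,
    correlate,
    fit_circular_fcs,
    fit_point_fcs,
    flcs_filters,
    merge_channels,
    multitau_lags,
    point_model,
    spot_variation,
)


def brute_force_correlation(times_s, weights, chunk_s, base_bin_s, max_lag_s, pts=8):
    """Independent oracle: explicit binned trace, explicit loops."""
    lags, levels = multitau_lags(base_bin_s, max_lag_s, pts)
    t0 = 0.0
    # same chunk-counting rule as the implementation (shared semantics)
    n_chunks = max(int((times_s.max() - t0) / chunk_s + 0.01), 1)
    out = []
    for c in range(n_chunks):
        lo = t0 + c * chunk_s
        sel = (times_s >= lo) & (times_s < lo + chunk_s)
        m = int(round(chunk_s / base_bin_s))
        trace = np.zeros(m)
        for t, w in zip(times_s[sel], weights[sel]):
            k = min(int((t - lo) / base_bin_s), m - 1)
            trace[k] += w
        g = np.full(len(lags), np.nan)
        level = 0
        cur = trace.copy()
        for i, (d, lev) in enumerate(zip(lags, levels)):
            while lev > level:
                mm = len(cur) - (len(cur) % 2)
                cur = cur[:mm].reshape(-1, 2).sum(axis=1)
                level += 1
            M = len(cur)
            if d >= M:
                continue
            s = 0.0
            for b in range(M - d):
                s += cur[b] * cur[b + d]
            wh = cur[: M - d].sum()
            wt = cur[d:].sum()
            if wh > 0 and wt > 0:
                g[i] = s * (M - d) / (wh * wt) - 1.0
        out.append(g)
    return np.nanmean(np.array(out), axis=0)


class TestChannelSelection:
    def test_sum5x5_is_21_channels(self):
        assert len(channel_selection("sum5x5")) == 21

    def test_sum3x3_is_centre_block(self):
        assert channel_selection("sum3x3") == [6, 7, 8, 11, 12, 13, 16, 17, 18]

    def test_central(self):
        assert channel_selection("central") == [12]

    def test_corners_excluded(self):
        sel = channel_selection("sum5x5")
        assert not set(sel) & {0, 4, 20, 24}

    def test_unknown_rejected(self):
        with pytest.raises(ValueError, match="unknown"):
            channel_selection("sum7x7")


class TestMergeChannels:
    @staticmethod
    def _tables(rng, per_channel=50):
        from ttmkit.tables import CHANNEL_CAL_DTYPE, MAIN_CAL_DTYPE, EventTables

        n = per_channel * 25
        main = np.empty(n, dtype=MAIN_CAL_DTYPE)
        main["idx"] = np.arange(n)
        main["t_sync_ns"] = np.sort(rng.random(n) * 1e9)
        for name in ("n_sync", "stop_code", "x", "y", "fr"):
            main[name] = 0
        chans = []
        for c in range(25):
            rows = np.empty(per_channel, dtype=CHANNEL_CAL_DTYPE)
            rows["idx"] = np.arange(per_channel) * 25 + c
            rows["dn"] = 0
            rows["start_code"] = 0
            rows["dt_ns"] = rng.random(per_channel) * 25.0
            chans.append(rows)
        return EventTables(main=main, channels=chans, calibrated=True)

    def test_merge_preserves_counts_and_order(self, rng):
        t = self._tables(rng)
        pl = merge_channels(t, "sum5x5")
        assert pl.times_s.size == 21 * 50
        assert (np.diff(pl.times_s) >= 0).all()

    def test_merge_single_channel(self, rng):
        t = self._tables(rng)
        pl = merge_channels(t, [12])
        assert pl.times_s.size == 50

    def test_merge_empty_selection_plus_one(self, rng):
        t = self._tables(rng)
        for c in range(25):
            if c != 12:
                t.channels[c] = t.channels[c][:0]
        pl = merge_channels(t, "sum5x5")
        assert pl.times_s.size == 50  # merge([A], []) = [A]


class TestCorrelator:
    def test_matches_brute_force_oracle_unit_weights(self, rng):
        times = np.sort(rng.random(5000) * 4.0)
        pl = PhotonTimeList(times_s=times)
        curve = correlate(pl, chunk_s=2.0, base_bin_s=1e-3, max_lag_s=0.2,
                          reject_outliers=False)
        oracle = brute_force_correlation(times, np.ones(5000), 2.0, 1e-3, 0.2)
        assert np.allclose(curve.G, oracle, rtol=1e-10, atol=1e-12, equal_nan=True)

    def test_matches_brute_force_oracle_weighted(self, rng):
        times = np.sort(rng.random(3000) * 4.0)
        weights = rng.random(3000) * 2 - 0.3
        pl = PhotonTimeList(times_s=times, weights=weights)
        curve = correlate(pl, chunk_s=2.0, base_bin_s=1e-3, max_lag_s=0.2,
                          reject_outliers=False)
        oracle = brute_force_correlation(times, weights, 2.0, 1e-3, 0.2)
        assert np.allclose(curve.G, oracle, rtol=1e-8, atol=1e-10, equal_nan=True)

    def test_unit_weights_equal_no_weights(self, rng):
        times = np.sort(rng.random(4000) * 4.0)
        a = correlate(PhotonTimeList(times_s=times), chunk_s=2.0, max_lag_s=0.1,
                      base_bin_s=1e-4, reject_outliers=False)
        b = correlate(PhotonTimeList(times_s=times, weights=np.ones(4000)),
                      chunk_s=2.0, max_lag_s=0.1, base_bin_s=1e-4, reject_outliers=False)
        assert np.array_equal(a.G, b.G)

    def test_poisson_photons_uncorrelated(self, rng):
        times = np.sort(rng.random(200_000) * 20.0)
        curve = correlate(PhotonTimeList(times_s=times), chunk_s=5.0,
                          base_bin_s=1e-5, max_lag_s=0.5)
        assert np.nanmax(np.abs(curve.G)) < 0.02

    def test_identical_chunks_average_equals_single(self, rng):
        base = np.sort(rng.random(2000))
        times = np.concatenate([base, base + 1.0, base + 2.0])
        curve = correlate(PhotonTimeList(times_s=times), chunk_s=1.0,
                          base_bin_s=1e-3, max_lag_s=0.05, reject_outliers=False)
        finite = np.isfinite(curve.chunk_G).all(axis=0)
        for c in range(3):
            assert np.allclose(curve.chunk_G[c][finite], curve.G[finite])
        assert np.allclose(curve.G_sd[finite], 0.0, atol=1e-12)

    def test_outlier_chunk_rejected(self, rng):
        quiet = np.sort(rng.random(3000) * 8.0)
        burst = np.sort(8.0 + rng.random(50_000) * 1.0)
        times = np.concatenate([quiet, burst])
        curve = correlate(PhotonTimeList(times_s=times), chunk_s=1.0,
                          base_bin_s=1e-3, max_lag_s=0.05)
        assert not curve.chunk_kept[8]
        assert curve.chunk_kept[:8].all()

    def test_empty_list_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            correlate(PhotonTimeList(times_s=np.empty(0)))

    def test_lag_grid_strictly_increasing(self):
        lags, levels = multitau_lags(1e-6, 1.0, 8)
        tau = lags * 1e-6 * 2.0**levels
        assert (np.diff(tau) > 0).all()

    def test_one_baseline_conversion(self):
        assert np.allclose(flfs.to_one_baseline(np.array([0.0, 0.5])), [1.0, 1.5])


class TestFlcsFilters:
    @staticmethod
    def _dts(rng, n=200_000, tau=4.0, bg_frac=0.0, period=25.0):
        n_bg = int(n * bg_frac)
        dt = np.concatenate([
            rng.exponential(tau, n - n_bg) % period,
            rng.random(n_bg) * period,
        ])
        return dt

    def test_pure_decay_filters_trivial(self, rng):
        f = flcs_filters(self._dts(rng), 25.0, bin_width_ns=0.2)
        r = f.retained
        assert np.allclose(f.fluor[r], 1.0, atol=0.05)
        assert np.allclose(f.background[r], 0.0, atol=0.05)

    def test_partition_property(self, rng):
        f = flcs_filters(self._dts(rng, bg_frac=0.4), 25.0, bin_width_ns=0.2)
        r = f.retained
        assert np.allclose(f.fluor[r] + f.background[r], 1.0, atol=1e-6)

    def test_early_photons_weigh_more(self, rng):
        f = flcs_filters(self._dts(rng, bg_frac=0.4), 25.0, bin_width_ns=0.2)
        w = f.photon_weights(np.array([0.5, 8.0]) + f.bin_edges_ns[0])
        assert w[0] > w[1]

    def test_photons_outside_crop_get_zero_weight(self, rng):
        f = flcs_filters(self._dts(rng, bg_frac=0.2), 25.0, bin_width_ns=0.2)
        w = f.photon_weights(np.array([f.bin_edges_ns[-1] + 5.0]))
        assert w[0] == 0.0

    def test_unbiasedness_of_filtered_sums(self, rng):
        # FLCS construction: filter-weighted histogram sums recover the
        # component amplitudes (checked against the fitted decomposition)
        dts = self._dts(rng, n=400_000, bg_frac=0.3)
        f = flcs_filters(dts, 25.0, bin_width_ns=0.2)
        w = f.photon_weights(dts)
        in_crop = (dts >= f.bin_edges_ns[0]) & (dts < f.bin_edges_ns[-1])
        # weights of retained photons sum to the fluorescence count estimate
        width = f.bin_edges_ns[1] - f.bin_edges_ns[0]
        t_rel = f.bin_edges_ns[:-1] - f.bin_edges_ns[0] + width / 2
        expected_fluor = f.amplitude * np.exp(-t_rel[f.retained] / f.tau_ns).sum()
        assert w.sum() == pytest.approx(expected_fluor, rel=0.05)


class TestFcsFits:
    @staticmethod
    def _curve_from_model(model_fn, noise=0.0, seed=0):
        lags, levels = multitau_lags(1e-6, 1.0, 8)
        tau = lags * 1e-6 * 2.0**levels
        g = model_fn(tau)
        if noise:
            g = g + np.random.default_rng(seed).normal(0, noise, g.size)
        return CorrelationCurve(
            tau_s=tau, G=g, G_sd=np.full_like(g, np.nan),
            chunk_G=g[None, :], chunk_kept=np.ones(1, bool),
            lag_width_s=1e-6 * 2.0**levels,
        )

    def test_point_fit_self_consistency(self):
        curve = self._curve_from_model(lambda t: point_model(t, 2.0, 1e-3, 4.5))
        fit = fit_point_fcs(curve, 0.3, 4.5)
        assert fit.N == pytest.approx(2.0, rel=1e-6)
        assert fit.tau_d_s == pytest.approx(1e-3, rel=1e-6)

    def test_printed_diffusion_relation(self):
        curve = self._curve_from_model(lambda t: point_model(t, 1.0, 1.5e-3, 4.5))
        fit = fit_point_fcs(curve, 0.3, 4.5)
        # D = w0^2 / (4 tau_D) = 0.09 / 6e-3 = 15
        assert fit.D_um2_s == pytest.approx(15.0, rel=1e-6)

    def test_circular_reduces_to_point_at_zero_radius(self):
        tau = np.logspace(-6, 0, 50)
        a = circular_model(tau, 2.0, 1e-3, 0.3, 4.5, 0.0, 1e-3)
        b = point_model(tau, 2.0, 1e-3, 4.5)
        assert np.allclose(a, b)

    def test_scanning_factor_unity_at_scan_period_multiples(self):
        T = 1e-3
        for m in (1, 2, 5):
            a = circular_model(np.array([m * T]), 2.0, 1e-3, 0.3, 4.5, 0.5, T)
            b = point_model(np.array([m * T]), 2.0, 1e-3, 4.5)
            assert a[0] == pytest.approx(b[0], rel=1e-12)

    def test_circular_fit_recovers_noiseless_model(self):
        true = dict(N=1.5, td=1.2e-3, w0=0.32)
        curve = self._curve_from_model(
            lambda t: circular_model(t, true["N"], true["td"], true["w0"], 4.5, 0.5, 1e-3)
        )
        # noiseless curve sampled on the grid: bin-averaging means the fit
        # is approximate but tight
        fit = fit_circular_fcs(curve, 0.5, 1e-3, 4.5)
        assert fit.N == pytest.approx(true["N"], rel=0.02)
        assert fit.omega0_um == pytest.approx(true["w0"], rel=0.02)


class TestSpotVariation:
    @staticmethod
    def _fit(w0, td, k=4.5):
        return flfs.FcsFit(
            N=1.0, tau_d_s=td, omega0_um=w0, k=k, D_um2_s=w0**2 / (4 * td),
            concentration_um3=1.0,
        )

    def test_line_through_origin(self):
        # three (w0^2, tauD) points on a line with slope 1/(4*15)
        fits = {
            "central": self._fit(0.3, 0.09 / 60.0),
            "sum3x3": self._fit(0.35, 0.1225 / 60.0),
            "sum5x5": self._fit(0.4, 0.16 / 60.0),
        }
        sv = spot_variation(fits)
        assert sv.intercept_s == pytest.approx(0.0, abs=1e-12)
        assert sv.D_from_slope_um2_s == pytest.approx(15.0, rel=1e-9)
        for d in sv.D_per_class.values():
            assert d == pytest.approx(15.0, rel=1e-9)

    def test_same_d_gives_unit_ratio(self):
        fits = {"a": self._fit(0.3, 1.5e-3), "b": self._fit(0.4, 0.16 / 0.09 * 1.5e-3)}
        sv = spot_variation(fits)
        assert sv.ratio_central_to_largest == pytest.approx(1.0)

    def test_needs_two_classes(self):
        with pytest.raises(ValueError, match="two"):
            spot_variation({"only": self._fit(0.3, 1e-3)})


class TestLifetimeVsTime:
    def test_step_change_detected(self, rng):
        # lifetime steps 4 -> 2 ns at t = 10 s
        n = 80_000
        times = np.sort(rng.random(n) * 20.0)
        dts = np.where(times < 10.0,
                       rng.exponential(4.0, n), rng.exponential(2.0, n)) % 25.0
        pl = PhotonTimeList(times_s=times, dt_ns=dts)
        out = flfs.lifetime_vs_time(
            {"central": pl, "sum5x5": pl}, 5.0,
            {"central": 0.3, "sum5x5": 0.4}, {"central": 4.5, "sum5x5": 4.1},
        )
        assert out["mask"].all()
        assert np.allclose(out["tau_fl_ns"][:2], 4.0, rtol=0.1)
        assert np.allclose(out["tau_fl_ns"][2:], 2.0, rtol=0.1)

    def test_sparse_window_masked(self, rng):
        times = np.sort(rng.random(200) * 10.0)
        pl = PhotonTimeList(times_s=times, dt_ns=rng.exponential(4.0, 200) % 25.0)
        out = flfs.lifetime_vs_time(
            {"a": pl, "b": pl}, 5.0, {"a": 0.3, "b": 0.4}, {"a": 4.5, "b": 4.1},
            min_photons=1000,
        )
        assert not out["mask"].any()
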