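import numpy as np
import pytest

from ttmkit import flism
from ttmkit.tables import CHANNEL_CAL_DTYPE, MAIN_CAL_DTYPE, EventTables


def synthetic_tables(rng, n_photons=1000, nx=8, ny=8, n_channels=25, period=25.0):
    """Calibrated tables with random photons on a small scan grid."""
    main = np.empty(n_photons, dtype=MAIN_CAL_DTYPE)
    main["idx"] = np.arange(n_photons)
    main["n_sync"] = np.sort(rng.integers(0, 10**6, n_photons))
    main["stop_code"] = rng.integers(0, 87, n_photons)
    main["x"] = rng.integers(0, nx, n_photons)
    main["y"] = rng.integers(0, ny, n_photons)
    main["fr"] = 0
    main["t_sync_ns"] = main["n_sync"] * 4.1667
    chans = []
    owner = rng.integers(0, n_channels, n_photons)
    for c in range(n_channels):
        idx = np.flatnonzero(owner == c)
        rows = np.empty(idx.size, dtype=CHANNEL_CAL_DTYPE)
        rows["idx"] = idx
        rows["dn"] = 1
        rows["start_code"] = rng.integers(0, 87, idx.size)
        rows["dt_ns"] = rng.exponential(4.0, idx.size) % period
        chans.append(rows)
    return EventTables(
        main=main, channels=chans, laser_period_ns=period, calibrated=True
    )


class TestBin4d:
    def test_photon_count_conserved(self, rng):
        t = synthetic_tables(rng, 1000)
        ds = flism.bin_4d(t, 8, 8, 1, bin_width_ns=0.4)
        assert ds.counts.sum() == 1000

    def test_all_photons_at_dt_zero_occupy_one_bin(self, rng):
        t = synthetic_tables(rng, 500)
        for rows in t.channels:
            rows["dt_ns"] = 0.0
        ds = flism.bin_4d(t, 8, 8, 1, bin_width_ns=0.4)
        occupied = np.nonzero(ds.counts.sum(axis=(0, 1, 2, 3)))[0]
        assert list(occupied) == [0]

    def test_marginal_matches_direct_histogram(self, rng):
        t = synthetic_tables(rng, 2000)
        ds = flism.bin_4d(t, 8, 8, 1, bin_width_ns=0.4)
        dts = np.concatenate([rows["dt_ns"] for rows in t.channels])
        direct, _ = np.histogram(dts % 25.0, bins=ds.counts.shape[-1], range=(0, ds.counts.shape[-1] * 0.4))
        assert np.array_equal(ds.counts.sum(axis=(0, 1, 2, 3)), direct)

    def test_uncalibrated_tables_rejected(self, rng):
        t = synthetic_tables(rng, 10)
        t.calibrated = False
        with pytest.raises(ValueError, match="calibrated"):
            flism.bin_4d(t, 8, 8)


def gaussian_scene(shift=(0.0, 0.0), n=64, seed=0):
    rng = np.random.default_rng(seed)
    img = np.zeros((n, n))
    xs, ys = np.meshgrid(np.arange(n, dtype=float), np.arange(n, dtype=float), indexing="ij")
    for _ in range(8):
        cx, cy = rng.random(2) * (n - 16) + 8
        img += 200 * np.exp(-(((xs - cx - shift[0]) ** 2) + (ys - cy - shift[1]) ** 2) / (2 * 2.0**2))
    return img


class TestRegisterChannels:
    def test_identical_images_zero_shift(self):
        img = gaussian_scene()
        fp = flism.register_channels(np.stack([img, img, img]), ref_channel=1)
        assert np.allclose(fp.sx, 0) and np.allclose(fp.sy, 0)

    def test_constructed_translation_recovered(self):
        imgs = np.stack([gaussian_scene((2.0, -1.0)), gaussian_scene(), gaussian_scene((-0.6, 0.4))])
        fp = flism.register_channels(imgs, ref_channel=1)
        assert fp.sx[0] == pytest.approx(2.0, abs=0.1)
        assert fp.sy[0] == pytest.approx(-1.0, abs=0.1)
        assert fp.sx[2] == pytest.approx(-0.6, abs=0.1)

    def test_featureless_image_flagged(self):
        img = gaussian_scene()
        fp = flism.register_channels(np.stack([np.zeros_like(img), img]), ref_channel=1)
        assert fp.sx[0] == 0 and fp.confidence[0] == 0


class TestAprReconstruct:
    @staticmethod
    def _dataset(shifts, n=48, nt=8, seed=3):
        imgs = [gaussian_scene(s, n=n, seed=seed) for s in shifts]
        counts = np.stack(imgs)[:, :, :, None, None] * np.ones(nt) / nt
        return flism.IsmDataset(counts=counts, bin_width_ns=25.0 / nt, laser_period_ns=25.0)

    def test_zero_shift_equals_channel_sum(self):
        ds = self._dataset([(0, 0), (0, 0)])
        fp = flism.ShiftFingerprint(sx=np.zeros(2), sy=np.zeros(2))
        out = flism.apr_reconstruct(ds, fp)
        assert np.allclose(out, ds.channel_sum(), atol=1e-8)

    def test_counts_conserved_within_half_percent(self):
        shifts = [(1.2, -0.7), (0, 0), (-0.8, 0.9)]
        ds = self._dataset(shifts)
        fp = flism.ShiftFingerprint(
            sx=np.array([s[0] for s in shifts]), sy=np.array([s[1] for s in shifts])
        )
        out = flism.apr_reconstruct(ds, fp)
        assert out.sum() == pytest.approx(ds.counts.sum(), rel=0.005)

    def test_reassigned_psf_narrower_than_open_sum(self):
        # single point source seen by three displaced channels
        n = 48
        xs, ys = np.meshgrid(np.arange(n, dtype=float), np.arange(n, dtype=float), indexing="ij")
        shifts = [(3.0, 0.0), (0.0, 0.0), (-3.0, 0.0)]
        imgs = [
            1000 * np.exp(-(((xs - 24 - s[0]) ** 2) + (ys - 24 - s[1]) ** 2) / (2 * 2.0**2))
            for s in shifts
        ]
        counts = np.stack(imgs)[:, :, :, None, None]
        ds = flism.IsmDataset(counts, 25.0, 25.0)
        fp = flism.ShiftFingerprint(
            sx=np.array([3.0, 0.0, -3.0]), sy=np.zeros(3)
        )
        apr = flism.apr_reconstruct(ds, fp)[:, :, 0]
        open_sum = ds.channel_sum()[:, :, 0]

        def fwhm_x(img):
            prof = img[:, 24]
            half = prof.max() / 2
            above = np.flatnonzero(prof >= half)
            return above[-1] - above[0]

        assert fwhm_x(apr) < fwhm_x(open_sum)


class TestLifetimeMap:
    def test_uniform_lifetime_phantom(self, rng):
        nt, width = 128, 0.195
        centers = (np.arange(nt) + 0.5) * width
        decay = np.exp(-centers / 3.0)
        lam = decay / decay.sum() * 3000
        cube = rng.poisson(lam, size=(6, 6, nt)).astype(float)
        lt = flism.fit_lifetime_map(cube, width, min_counts=100)
        assert lt.mask.all()
        assert np.nanmean(lt.tau_ns) == pytest.approx(3.0, rel=0.05)

    def test_two_region_phantom_bimodal(self, rng):
        nt, width = 128, 0.195
        centers = (np.arange(nt) + 0.5) * width
        cube = np.empty((4, 8, nt))
        for tau, sl in ((2.0, np.s_[:, :4]), (4.0, np.s_[:, 4:])):
            decay = np.exp(-centers / tau)
            cube[sl] = rng.poisson(decay / decay.sum() * 5000, size=(4, 4, nt))
        lt = flism.fit_lifetime_map(cube, width)
        assert np.nanmedian(lt.tau_ns[:, :4]) == pytest.approx(2.0, rel=0.1)
        assert np.nanmedian(lt.tau_ns[:, 4:]) == pytest.approx(4.0, rel=0.1)

    def test_zero_count_pixel_masked(self):
        cube = np.zeros((2, 2, 64))
        cube[0, 0, :] = 100
        lt = flism.fit_lifetime_map(cube, 0.4, min_counts=50)
        assert lt.mask[0, 0]
        assert not lt.mask[1, 1]
        assert np.isnan(lt.tau_ns[1, 1])


class TestPhasor:
    @staticmethod
    def folded_decay_hist(tau, period=25.0, nt=520, delay=0.0):
        width = period / nt
        centers = (np.arange(nt) + 0.5) * width
        # analytic bin integral of the periodically folded decay
        edges = np.arange(nt + 1) * width
        cdf = lambda t: 1 - np.exp(-t / tau)
        h = cdf(np.mod(edges[1:] - delay, period)) - cdf(np.mod(edges[:-1] - delay, period))
        h = np.where(h < 0, h + cdf(period), h)
        return h / (1 - np.exp(-period / tau))

    def test_closed_form_semicircle_position(self):
        # tau = 4.1 ns at 40 MHz: (g, s) = (0.4850, 0.4998)
        h = self.folded_decay_hist(4.1)
        g, s = flism.phasor_transform(h, 25.0 / 520, 25.0)
        ge, se = flism.phasor_of_exponential(4.1, 25.0)
        assert ge == pytest.approx(0.4850, abs=2e-4)
        assert se == pytest.approx(0.4998, abs=2e-4)
        assert g == pytest.approx(ge, abs=2e-3)
        assert s == pytest.approx(se, abs=2e-3)

    def test_semicircle_endpoints(self):
        g0, s0 = flism.phasor_of_exponential(1e-9, 25.0)
        ginf, sinf = flism.phasor_of_exponential(1e9, 25.0)
        assert (g0, s0) == (pytest.approx(1.0), pytest.approx(0.0, abs=1e-6))
        assert (ginf, sinf) == (pytest.approx(0.0), pytest.approx(0.0, abs=1e-6))

    def test_noiseless_exponential_on_semicircle(self):
        for tau in (1.0, 2.5, 4.0, 8.0):
            h = self.folded_decay_hist(tau)
            g, s = flism.phasor_transform(h, 25.0 / 520, 25.0)
            assert (g - 0.5) ** 2 + s**2 == pytest.approx(0.25, abs=1e-3)

    def test_background_moves_point_toward_origin(self):
        h = self.folded_decay_hist(4.0)
        g1, s1 = flism.phasor_transform(h, 25.0 / 520, 25.0)
        hb = 0.7 * h + 0.3 / 520
        g2, s2 = flism.phasor_transform(hb, 25.0 / 520, 25.0)
        assert np.hypot(g2, s2) < np.hypot(g1, s1)
        # strictly toward the origin: same phase, smaller modulus
        assert np.arctan2(s2, g2) == pytest.approx(np.arctan2(s1, g1), abs=1e-6)

    def test_reference_correction_removes_instrument_phase(self):
        # simulate a fixed instrument delay on both sample and reference
        h_ref = self.folded_decay_hist(4.1, delay=1.3)
        h_smp = self.folded_decay_hist(2.0, delay=1.3)
        gr, sr = flism.phasor_transform(h_ref, 25.0 / 520, 25.0)
        g, s = flism.phasor_transform(h_smp, 25.0 / 520, 25.0)
        gc, sc = flism.phasor_reference_correction(g, s, gr, sr, 4.1, 25.0)
        ge, se = flism.phasor_of_exponential(2.0, 25.0)
        assert gc == pytest.approx(ge, abs=2e-3)
        assert sc == pytest.approx(se, abs=2e-3)


class TestFrc:
    def test_split_partitions_exactly(self, rng):
        t = synthetic_tables(rng, 5000)
        odd, even = flism.frc_split(t)
        assert odd.n_photons + even.n_photons == t.n_photons
        for c in range(t.n_channels):
            assert (odd.channels[c]["start_code"] % 2 == 1).all()
            assert (even.channels[c]["start_code"] % 2 == 0).all()

    def test_split_sizes_binomial_bound(self, rng):
        t = synthetic_tables(rng, 20_000)
        odd, even = flism.frc_split(t)
        n = t.n_photons
        # uniform tap occupancy: |n_odd - n/2| within 4 sqrt(n)
        assert abs(odd.n_photons - n / 2) < 4 * np.sqrt(n)

    def test_identical_images_never_cross(self):
        img = gaussian_scene()
        res = flism.frc_resolution(img, img)
        assert not res.crossed
        assert np.allclose(res.frc[np.isfinite(res.frc)], 1.0, atol=1e-9)

    def test_independent_noise_decorrelated(self, rng):
        a = rng.poisson(10.0, (64, 64)).astype(float)
        b = rng.poisson(10.0, (64, 64)).astype(float)
        res = flism.frc_resolution(a, b)
        assert np.nanmean(np.abs(res.frc)) < 0.15
        assert res.crossed

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError, match="shape"):
            flism.frc_resolution(np.zeros((8, 8)), np.zeros((8, 9)))

    def test_noisy_scene_resolves_better_with_more_signal(self, rng):
        scene = gaussian_scene(n=64)
        strong = [rng.poisson(scene * 4).astype(float) for _ in range(2)]
        weak = [rng.poisson(scene * 0.05).astype(float) for _ in range(2)]
        r_strong = flism.frc_resolution(*strong)
        r_weak = flism.frc_resolution(*weak)
        assert r_strong.cutoff_freq > r_weak.cutoff_freq
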