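"""Lifetime image-scanning microscopy: 4D binning, pixel reassignment,
per-pixel lifetime fitting, phasor analysis, and FRC resolution.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from skimage.registration import phase_cross_correlation

from ._fitting import fit_exp_decay
from .tables import EventTables

log = logging.getLogger(__name__)

FRC_THRESHOLD = 1.0 / 7.0  # fixed-threshold criterion


@dataclass
class IsmDataset:
    """Photon counts over (ch, x, y, fr, dt-bin)."""

    counts: np.ndarray
    bin_width_ns: float
    laser_period_ns: float

    @property
    def n_channels(self) -> int:
        return self.counts.shape[0]

    def images(self) -> np.ndarray:
        """Per-channel intensity images, integrated over frames and dt."""
        return self.counts.sum(axis=(3, 4))

    def channel_sum(self) -> np.ndarray:
        """Open (unshifted) sum over channels and frames -> (x, y, dt)."""
        return self.counts.sum(axis=(0, 3))


def bin_4d(
    tables: EventTables,
    nx: int,
    ny: int,
    n_frames: int = 1,
    bin_width_ns: float = 0.048,
) -> IsmDataset:
    """Bin calibrated photons into the (ch, x, y, fr, dt) counts array.

    Left-edge binning of the start--stop time after MOD with the laser
    period; photons outside the scan grid (x or y or fr < 0) are skipped.
    """
    if not tables.calibrated:
        raise ValueError("bin_4d needs calibrated tables")
    period = tables.laser_period_ns
    n_bins = int(np.ceil(period / bin_width_ns))
    counts = np.zeros((tables.n_channels, nx, ny, n_frames, n_bins), dtype=np.uint32)
    main = tables.main
    for ch, rows in enumerate(tables.channels):
        if rows.size == 0:
            continue
        x = main["x"][rows["idx"]]
        y = main["y"][rows["idx"]]
        fr = main["fr"][rows["idx"]]
        ok = (x >= 0) & (x < nx) & (y >= 0) & (y < ny) & (fr >= 0) & (fr < n_frames)
        tbin = np.minimum(
            (np.mod(rows["dt_ns"][ok], period) / bin_width_ns).astype(np.int64),
            n_bins - 1,
        )
        np.add.at(counts[ch], (x[ok], y[ok], fr[ok], tbin), 1)
    return IsmDataset(counts=counts, bin_width_ns=bin_width_ns, laser_period_ns=period)


# ---------------------------------------------------------------------------
# adaptive pixel reassignment
# ---------------------------------------------------------------------------


@dataclass
class ShiftFingerprint:
    """Sub-pixel shift of each element's image relative to the centre one."""

    sx: np.ndarray
    sy: np.ndarray
    confidence: np.ndarray = None

    def __post_init__(self) -> None:
        if self.confidence is None:
            self.confidence = np.ones(len(self.sx))


def register_channels(
    images: np.ndarray, ref_channel: int | None = None, upsample: int = 50
) -> ShiftFingerprint:
    """Shift-vector fingerprint by upsampled phase correlation.

    ``images`` is (ch, nx, ny); each channel is registered against the
    central element.  Featureless channels get shift 0 with confidence 0.
    """
    images = np.asarray(images, dtype=float)
    n_ch = images.shape[0]
    if ref_channel is None:
        ref_channel = n_ch // 2
    ref = images[ref_channel]
    sx = np.zeros(n_ch)
    sy = np.zeros(n_ch)
    conf = np.ones(n_ch)
    for ch in range(n_ch):
        img = images[ch]
        if img.max() <= 0 or np.allclose(img, img.flat[0]):
            conf[ch] = 0.0
            continue
        # shift returned moves `img` onto `ref`; the fingerprint is the
        # displacement of img *relative to* ref, i.e. its negation.  Plain
        # cross-correlation (no spectral whitening) is unbiased on the
        # smooth, low-frequency images produced by a scanning microscope.
        shift, _, _ = phase_cross_correlation(
            ref, img, upsample_factor=upsample, normalization=None
        )
        sx[ch], sy[ch] = -shift[0], -shift[1]
    return ShiftFingerprint(sx=sx, sy=sy, confidence=conf)


def apr_reconstruct(dataset: IsmDataset, fingerprint: ShiftFingerprint) -> np.ndarray:
    """Pixel-reassigned (x, y, dt) cube.

    Every channel's (x, y) planes are translated by minus its fingerprint
    (the same shift for every dt bin, Fourier interpolation) and summed
    over channels and frames.  Total counts are conserved up to border
    interpolation loss.
    """
    cube = dataset.counts.sum(axis=3).astype(float)  # (ch, x, y, dt)
    out = np.zeros(cube.shape[1:], dtype=float)
    for ch in range(cube.shape[0]):
        plane = cube[ch]
        if not plane.any():
            continue
        f = np.fft.fftn(plane, axes=(0, 1))
        f = ndimage.fourier_shift(
            f, shift=(-fingerprint.sx[ch], -fingerprint.sy[ch], 0)
        )
        out += np.real(np.fft.ifftn(f, axes=(0, 1)))
    lost = dataset.counts.sum() - out.sum()
    if abs(lost) > 0.005 * max(dataset.counts.sum(), 1):
        log.info("APR border loss: %.1f counts", lost)
    return out


# ---------------------------------------------------------------------------
# lifetime fitting and phasors
# ---------------------------------------------------------------------------


@dataclass
class LifetimeMap:
    tau_ns: np.ndarray
    amplitude: np.ndarray
    offset: np.ndarray
    mask: np.ndarray  # True where fitted
    fit_ok: np.ndarray


def fit_lifetime_map(
    cube: np.ndarray,
    bin_width_ns: float,
    min_counts: int = 100,
    fit_window_ns: float = 10.0,
) -> LifetimeMap:
    """Per-pixel single-exponential (+offset) fit of the (x, y, dt) cube.

    Pixels with fewer than ``min_counts`` photons are masked out.
    """
    nx, ny, nt = cube.shape
    centers = (np.arange(nt) + 0.5) * bin_width_ns
    tau = np.full((nx, ny), np.nan)
    amp = np.full((nx, ny), np.nan)
    off = np.full((nx, ny), np.nan)
    ok = np.zeros((nx, ny), dtype=bool)
    mask = cube.sum(axis=2) >= min_counts
    for i, j in zip(*np.nonzero(mask)):
        a, t, b, good = fit_exp_decay(centers, cube[i, j], fit_window_ns)
        amp[i, j], tau[i, j], off[i, j], ok[i, j] = a, t, b, good
    return LifetimeMap(tau_ns=tau, amplitude=amp, offset=off, mask=mask, fit_ok=ok)


def phasor_transform(
    hist: np.ndarray,
    bin_width_ns: float,
    laser_period_ns: float,
    harmonic: int = 1,
    axis: int = -1,
    correct_binning: bool = True,
):
    """Phasor coordinates (g, s) of decay histograms at the laser harmonic.

    ``g = sum c cos(w t) / sum c``, ``s = sum c sin(w t) / sum c`` over bin
    centres.  With ``correct_binning`` the modulation loss of finite bins
    is undone by dividing by sinc(bin/period) (bin-centre convention keeps
    the phase exact).
    """
    hist = np.asarray(hist, dtype=float)
    nt = hist.shape[axis]
    w = 2 * np.pi * harmonic / laser_period_ns
    t = (np.arange(nt) + 0.5) * bin_width_ns
    shape = [1] * hist.ndim
    shape[axis] = nt
    cos = np.cos(w * t).reshape(shape)
    sin = np.sin(w * t).reshape(shape)
    total = hist.sum(axis=axis)
    with np.errstate(invalid="ignore", divide="ignore"):
        g = (hist * cos).sum(axis=axis) / total
        s = (hist * sin).sum(axis=axis) / total
    if correct_binning:
        demod = np.sinc(harmonic * bin_width_ns / laser_period_ns)
        g = g / demod
        s = s / demod
    return g, s


def phasor_of_exponential(tau_ns: float, laser_period_ns: float, harmonic: int = 1):
    """Closed-form semicircle position of a single-exponential decay."""
    wt = 2 * np.pi * harmonic / laser_period_ns * tau_ns
    return 1.0 / (1.0 + wt**2), wt / (1.0 + wt**2)


def phasor_reference_correction(g, s, g_ref, s_ref, tau_ref_ns, laser_period_ns, harmonic=1):
    """Re-reference measured phasors using a known-lifetime calibration run.

    Rotates and rescales by the complex ratio expected/measured of the
    reference, removing the instrument response (phase delay and
    demodulation).
    """
    z = np.asarray(g) + 1j * np.asarray(s)
    z_ref = complex(g_ref, s_ref)
    g_e, s_e = phasor_of_exponential(tau_ref_ns, laser_period_ns, harmonic)
    z_corr = z * complex(g_e, s_e) / z_ref
    return np.real(z_corr), np.imag(z_corr)


# ---------------------------------------------------------------------------
# Fourier ring correlation
# ---------------------------------------------------------------------------


def frc_split(tables: EventTables):
    """Split photons into two halves by START-code parity.

    The sliding scale distributes photons uniformly over the taps, so the
    two halves are statistically independent with similar counts.  Returns
    ``(tables_odd, tables_even)`` sharing the main table.
    """
    halves = []
    for parity in (1, 0):
        channels = [rows[(rows["start_code"] % 2) == parity] for rows in tables.channels]
        halves.append(
            EventTables(
                main=tables.main,
                channels=channels,
                t_sysclk_ns=tables.t_sysclk_ns,
                laser_period_ns=tables.laser_period_ns,
                discarded_photons=tables.discarded_photons,
                calibrated=tables.calibrated,
                attrs=dict(tables.attrs),
            )
        )
    return halves[0], halves[1]


@dataclass
class FrcResult:
    freqs: np.ndarray  # cycles per pixel (or per unit if pixel size given)
    frc: np.ndarray
    cutoff_freq: float
    resolution: float  # 1 / cutoff
    crossed: bool


def frc_resolution(img1: np.ndarray, img2: np.ndarray, pixel_size: float = 1.0,
                   threshold: float = FRC_THRESHOLD) -> FrcResult:
    """Fourier ring correlation between two half-data images.

    Ring-wise normalized cross-correlation of the two spectra; the
    resolution is the inverse of the first crossing below ``threshold``.
    If the curve never crosses, the Nyquist frequency is reported with
    ``crossed=False``.
    """
    img1 = np.asarray(img1, dtype=float)
    img2 = np.asarray(img2, dtype=float)
    if img1.shape != img2.shape:
        raise ValueError("images must have equal shape")
    n = img1.shape
    f1 = np.fft.fftshift(np.fft.fft2(img1 - img1.mean()))
    f2 = np.fft.fftshift(np.fft.fft2(img2 - img2.mean()))
    ky = np.fft.fftshift(np.fft.fftfreq(n[0]))
    kx = np.fft.fftshift(np.fft.fftfreq(n[1]))
    kr = np.sqrt(ky[:, None] ** 2 + kx[None, :] ** 2)
    n_rings = min(n) // 2
    ring = np.minimum((kr * 2 * n_rings).astype(int), n_rings)  # kr in [0, ~0.707]

    num = np.bincount(ring.ravel(), np.real(f1 * np.conj(f2)).ravel(), minlength=n_rings + 1)
    d1 = np.bincount(ring.ravel(), (np.abs(f1) ** 2).ravel(), minlength=n_rings + 1)
    d2 = np.bincount(ring.ravel(), (np.abs(f2) ** 2).ravel(), minlength=n_rings + 1)
    with np.errstate(invalid="ignore", divide="ignore"):
        frc = num / np.sqrt(d1 * d2)
    freqs = np.arange(n_rings + 1) / (2 * n_rings) / pixel_size
    frc = frc[1 : n_rings + 1]
    freqs = freqs[1 : n_rings + 1]
    # first raw crossing; ring correlations are near 1 with low variance
    # before the signal band ends, so spurious early dips are rare
    frc_s = frc

    below = np.flatnonzero(frc_s < threshold)
    if below.size == 0:
        return FrcResult(freqs, frc, float(freqs[-1]), float(1.0 / freqs[-1]), False)
    k = below[0]
    if k == 0:
        cutoff = freqs[0]
    else:
        f0, f1_ = freqs[k - 1], freqs[k]
        y0, y1 = frc_s[k - 1], frc_s[k]
        cutoff = f0 + (threshold - y0) * (f1_ - f0) / (y1 - y0)
    return FrcResult(freqs, frc, float(cutoff), float(1.0 / cutoff), True)
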