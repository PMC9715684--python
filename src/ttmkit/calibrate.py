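"""Code-density calibration, nonlinearity metrics, time reconstruction.

The statistical code-density test converts tap-code occupancies of
temporally uncorrelated events into tap widths: asynchronous events are
uniform over the clock period, so occupancy is proportional to width.
Code->time maps use the bin-centre convention: the time assigned to code
``k`` is the cumulative width below ``k`` plus half of ``k``'s own width.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import h5py
import numpy as np
from scipy.optimize import curve_fit

from .constants import LSB_PS, T_SYSCLK_NS

log = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# code-density calibration
# ---------------------------------------------------------------------------


@dataclass
class LineCalibration:
    """Code->time map of one delay line."""

    widths_ns: np.ndarray  # per-code width
    times_ns: np.ndarray  # bin-centre time per code

    @property
    def n_codes(self) -> int:
        return self.widths_ns.size


def code_density_calibrate(
    codes: np.ndarray,
    t_sysclk_ns: float = T_SYSCLK_NS,
    n_codes: int | None = None,
    min_events: int = 1000,
) -> LineCalibration:
    """Calibrate one delay line from tap codes of uncorrelated events.

    ``width_k = count_k / total * T_sysclk``; empty codes get zero width
    with a warning.  Requires at least ``min_events`` samples.
    """
    codes = np.asarray(codes)
    if codes.size < min_events:
        raise ValueError(f"need >= {min_events} events for code density, got {codes.size}")
    if n_codes is None:
        n_codes = int(codes.max()) + 1
    counts = np.bincount(codes, minlength=n_codes).astype(float)
    if (counts == 0).any():
        warnings.warn(
            f"{int((counts == 0).sum())} empty code bins set to zero width", stacklevel=2
        )
    widths = counts / counts.sum() * t_sysclk_ns
    times = np.cumsum(widths) - widths / 2.0
    return LineCalibration(widths_ns=widths, times_ns=times)


@dataclass
class NonlinearityReport:
    """DNL/INL of a delay line in LSB units."""

    dnl: np.ndarray
    inl: np.ndarray
    sigma_dnl: float
    sigma_inl: float
    lsb_ns: float


def nonlinearity(counts: np.ndarray, t_sysclk_ns: float = T_SYSCLK_NS) -> NonlinearityReport:
    """Differential and integral nonlinearity from per-code occupancies.

    ``dnl_k = width_k / LSB_ideal - 1`` with ``LSB_ideal = T / n_codes``;
    INL is the running sum.  Scale-invariant in the counts.
    """
    counts = np.asarray(counts, dtype=float)
    widths = counts / counts.sum() * t_sysclk_ns
    lsb = t_sysclk_ns / counts.size
    dnl = widths / lsb - 1.0
    inl = np.cumsum(dnl)
    return NonlinearityReport(
        dnl=dnl,
        inl=inl,
        sigma_dnl=float(dnl.std()),
        sigma_inl=float(inl.std()),
        lsb_ns=lsb,
    )


@dataclass
class CalibrationTable:
    """Per-channel START maps, the shared STOP map, and channel offsets."""

    start: list  # list[LineCalibration], one per channel
    stop: LineCalibration
    t_sysclk_ns: float = T_SYSCLK_NS
    lsb_ns: float = LSB_PS * 1e-3
    offsets_ns: np.ndarray = None  # per-channel global offset

    def __post_init__(self) -> None:
        if self.offsets_ns is None:
            self.offsets_ns = np.zeros(len(self.start))
        self.offsets_ns = np.asarray(self.offsets_ns, dtype=float)

    @property
    def n_channels(self) -> int:
        return len(self.start)

    @classmethod
    def from_tdl(cls, tdl) -> "CalibrationTable":
        """Exact table from a simulator TDL model (ground-truth widths)."""
        start = [
            LineCalibration(w.copy(), np.cumsum(w) - w / 2.0) for w in tdl.start_widths
        ]
        stop = LineCalibration(
            tdl.stop_widths.copy(), np.cumsum(tdl.stop_widths) - tdl.stop_widths / 2.0
        )
        return cls(start=start, stop=stop, t_sysclk_ns=tdl.clock_period)

    @classmethod
    def from_code_density(
        cls, start_codes: list, stop_codes: np.ndarray, t_sysclk_ns: float = T_SYSCLK_NS,
        n_codes: int | None = None,
    ) -> "CalibrationTable":
        start = [code_density_calibrate(c, t_sysclk_ns, n_codes) for c in start_codes]
        stop = code_density_calibrate(stop_codes, t_sysclk_ns, n_codes)
        return cls(start=start, stop=stop, t_sysclk_ns=t_sysclk_ns)

    def start_time(self, channel: int, code: np.ndarray) -> np.ndarray:
        return self.start[channel].times_ns[np.asarray(code)]

    def stop_time(self, code: np.ndarray) -> np.ndarray:
        return self.stop.times_ns[np.asarray(code)]

    def save(self, path) -> None:
        with h5py.File(path, "w") as f:
            f.attrs["t_sysclk_ns"] = self.t_sysclk_ns
            f.attrs["lsb_ns"] = self.lsb_ns
            f["offsets_ns"] = self.offsets_ns
            f["stop_widths_ns"] = self.stop.widths_ns
            f["start_widths_ns"] = np.stack([s.widths_ns for s in self.start])

    @classmethod
    def load(cls, path) -> "CalibrationTable":
        with h5py.File(path, "r") as f:
            stop_w = f["stop_widths_ns"][()]
            start_w = f["start_widths_ns"][()]
            table = cls(
                start=[LineCalibration(w, np.cumsum(w) - w / 2.0) for w in start_w],
                stop=LineCalibration(stop_w, np.cumsum(stop_w) - stop_w / 2.0),
                t_sysclk_ns=float(f.attrs["t_sysclk_ns"]),
                lsb_ns=float(f.attrs["lsb_ns"]),
                offsets_ns=f["offsets_ns"][()],
            )
        return table


# ---------------------------------------------------------------------------
# time reconstruction
# ---------------------------------------------------------------------------


def start_stop(dt_start_ns, dt_stop_ns, dn, t_sysclk_ns: float = T_SYSCLK_NS):
    """Start--stop time  dt_stop - dt_start + dn * T_sysclk  (ns).

    ``dn = n_SYNC - n_photon`` must be >= 0; a negative result with
    ``dn == 0`` marks a mis-association (caller should re-match).
    """
    dn = np.asarray(dn)
    if (dn < 0).any():
        raise ValueError("dn must be >= 0 (SYNC follows the photon)")
    return np.asarray(dt_stop_ns) - np.asarray(dt_start_ns) + dn * t_sysclk_ns


def coarse_time(n, t_sysclk_ns: float = T_SYSCLK_NS):
    """Coarse absolute time  n * T_sysclk  (ns)."""
    return np.asarray(n) * t_sysclk_ns


def ref_delay(n_photon, n_ref, t_sysclk_ns: float = T_SYSCLK_NS):
    """Coarse delay of a photon from a REF event, (n_photon - n_ref) * T."""
    return (np.asarray(n_photon) - np.asarray(n_ref)) * t_sysclk_ns


# ---------------------------------------------------------------------------
# single-shot precision
# ---------------------------------------------------------------------------


@dataclass
class SspResult:
    sigma_ns: float
    center_ns: float
    fit_ok: bool
    histogram: tuple = field(repr=False, default=())


def _gauss(x, a, mu, sig):
    return a * np.exp(-0.5 * ((x - mu) / sig) ** 2)


def single_shot_precision(samples_ns: np.ndarray, bin_ns: float = LSB_PS * 1e-3) -> SspResult:
    """Gaussian-fit sigma of repeated measurements of a constant delay.

    Least-squares fit with Poisson weights on the histogram; falls back to
    the sample standard deviation if the fit fails.  Warns when the
    histogram looks non-unimodal.
    """
    samples = np.asarray(samples_ns, dtype=float)
    if samples.size < 100:
        raise ValueError("need >= 100 samples for a precision estimate")
    lo, hi = samples.min(), samples.max()
    edges = np.arange(lo - bin_ns, hi + 2 * bin_ns, bin_ns)
    counts, edges = np.histogram(samples, bins=edges)
    centers = 0.5 * (edges[:-1] + edges[1:])

    peaks = np.flatnonzero(
        (counts[1:-1] > counts[:-2]) & (counts[1:-1] >= counts[2:]) & (counts[1:-1] > counts.max() * 0.5)
    )
    if peaks.size > 1 and np.ptp(peaks) > 2:
        warnings.warn("start-stop histogram looks non-unimodal; fit may be poor", stacklevel=2)

    p0 = (counts.max(), samples.mean(), max(samples.std(), bin_ns))
    try:
        sigma_w = np.sqrt(np.maximum(counts, 1.0))
        popt, _ = curve_fit(_gauss, centers, counts, p0=p0, sigma=sigma_w, maxfev=10000)
        return SspResult(abs(popt[2]), popt[1], True, (counts, edges))
    except RuntimeError:
        return SspResult(float(samples.std()), float(samples.mean()), False, (counts, edges))


def pairwise_precision(samples_a_ns, samples_b_ns, bin_ns: float = LSB_PS * 1e-3) -> SspResult:
    """Dual-channel variant: precision of the A-B time-difference histogram."""
    a = np.asarray(samples_a_ns, float)
    b = np.asarray(samples_b_ns, float)
    n = min(a.size, b.size)
    return single_shot_precision(a[:n] - b[:n], bin_ns)


# ---------------------------------------------------------------------------
# inter-channel alignment
# ---------------------------------------------------------------------------


def _phasor_phase(hist, centers, period):
    w = 2 * np.pi / period
    z = np.sum(hist * np.exp(1j * w * centers))
    return np.angle(z)


def align_channels(
    histograms: np.ndarray,
    bin_centers_ns: np.ndarray,
    laser_period_ns: float,
    tau_ref_ns: float = 4.1,
    min_counts: int = 100,
) -> np.ndarray:
    """Per-channel time offsets from a reference single-exponential run.

    The phase difference between each channel's measured phasor and the
    expected phasor of the reference lifetime gives the channel delay:
    ``offset = (phi_measured - arctan(w tau_ref)) / w``.  Channels with
    fewer than ``min_counts`` counts get offset 0 with a warning.
    """
    histograms = np.atleast_2d(np.asarray(histograms, dtype=float))
    w = 2 * np.pi / laser_period_ns
    phi_ref = np.arctan(w * tau_ref_ns)
    offsets = np.zeros(histograms.shape[0])
    for ch, h in enumerate(histograms):
        if h.sum() < min_counts:
            warnings.warn(f"channel {ch}: <{min_counts} counts, offset set to 0", stacklevel=2)
            continue
        phi = _phasor_phase(h, bin_centers_ns, laser_period_ns)
        # phase wrapped to (-pi, pi]; bring the offset into +/- half period
        d = phi - phi_ref
        d = (d + np.pi) % (2 * np.pi) - np.pi
        offsets[ch] = d / w
    return offsets


def shift_histogram(hist: np.ndarray, offset_ns: float, bin_width_ns: float) -> np.ndarray:
    """Circularly shift a histogram back by ``offset_ns`` (Fourier phase).

    Bin-width independent: sub-bin shifts are interpolated in frequency
    space, as used to re-align per-channel decay histograms.
    """
    n = hist.size
    freq = np.fft.fftfreq(n, d=bin_width_ns)
    return np.real(np.fft.ifft(np.fft.fft(hist) * np.exp(2j * np.pi * freq * offset_ns)))
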