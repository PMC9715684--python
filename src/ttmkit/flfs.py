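"""Lifetime fluctuation spectroscopy: weighted timestamp correlation,
FLCS filter construction, point and circular-scanning FCS fits, and the
spot-variation diffusion law.

Correlator semantics: photon timestamps are quantized on a base bin
(default 1 us) and correlated on a quasi-logarithmic multi-tau grid with
coarsening-by-two cascades.  The estimator per lag ``d`` (in bins of
width ``delta``) is the 0-baseline fluctuation form with symmetric edge
normalization::

    G(d*delta) = S_d * (M - d) / (W_head * W_tail) - 1,
    S_d = sum_b w_b w_{b+d},  W_head = sum_{b < M-d} w_b,
    W_tail = sum_{b >= d} w_b

which for unit weights reduces to the classic photon-mode estimator and is
reproduced exactly by a brute-force binned-trace computation.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy.optimize import curve_fit

from ._fitting import decay_histogram, fit_exp_decay
from .tables import EventTables

log = logging.getLogger(__name__)

_SUM3X3 = [6, 7, 8, 11, 12, 13, 16, 17, 18]
_CORNERS_5X5 = [0, 4, 20, 24]


@dataclass
class PhotonTimeList:
    """Sorted absolute photon times with optional weights and decay times."""

    times_s: np.ndarray
    dt_ns: np.ndarray = None
    weights: np.ndarray = None
    label: str = "custom"

    def __post_init__(self) -> None:
        self.times_s = np.asarray(self.times_s, dtype=float)
        if np.any(np.diff(self.times_s) < 0):
            raise ValueError("times must be sorted non-decreasing")
        if self.weights is not None:
            self.weights = np.asarray(self.weights, dtype=float)
            if not np.isfinite(self.weights).all():
                raise ValueError("weights must be finite")


def channel_selection(selection, n_channels: int = 25):
    """Resolve 'central' | 'sum3x3' | 'sum5x5' | iterable into indices."""
    if isinstance(selection, str):
        if selection == "central":
            return [n_channels // 2]
        if selection == "sum3x3":
            return list(_SUM3X3)
        if selection == "sum5x5":
            return [c for c in range(n_channels) if c not in _CORNERS_5X5]
        raise ValueError(f"unknown selection {selection!r}")
    return sorted(int(c) for c in selection)


def merge_channels(tables: EventTables, selection) -> PhotonTimeList:
    """Merge and sort the photon time lists of the selected elements.

    Absolute time is the calibrated ``t_sync`` of each photon's associated
    SYNC event (the stored tables already carry everything needed).
    """
    if not tables.calibrated:
        raise ValueError("merge_channels needs calibrated tables")
    chans = channel_selection(selection, tables.n_channels)
    t_parts, dt_parts = [], []
    for ch in chans:
        rows = tables.channels[ch]
        t_parts.append(tables.main["t_sync_ns"][rows["idx"]])
        dt_parts.append(rows["dt_ns"])
    t = np.concatenate(t_parts) if t_parts else np.empty(0)
    dt = np.concatenate(dt_parts) if dt_parts else np.empty(0)
    order = np.argsort(t, kind="stable")
    label = selection if isinstance(selection, str) else "custom"
    return PhotonTimeList(times_s=t[order] * 1e-9, dt_ns=dt[order], label=label)


# ---------------------------------------------------------------------------
# correlator
# ---------------------------------------------------------------------------


@dataclass
class CorrelationCurve:
    """Quasi-log lag grid with averaged G and per-chunk curves."""

    tau_s: np.ndarray
    G: np.ndarray
    G_sd: np.ndarray
    chunk_G: np.ndarray  # (n_chunks, n_lags)
    chunk_kept: np.ndarray  # outlier-rejection mask
    lag_width_s: np.ndarray  # averaging width of each lag (cascade level bin)


def to_one_baseline(G: np.ndarray) -> np.ndarray:
    """Convert the 0-baseline fluctuation form to the 1-baseline display
    convention, G1(tau) = G(tau) + 1."""
    return np.asarray(G) + 1.0


def multitau_lags(base_bin_s: float, max_lag_s: float, pts_per_level: int = 8):
    """(lag in bins, level) pairs of the multi-tau cascade."""
    lags, levels = [], []
    d = np.arange(1, pts_per_level + 1)
    level = 0
    while True:
        delta = base_bin_s * 2**level
        sel = d if level == 0 else d[pts_per_level // 2 :]
        for dd in sel:
            if dd * delta > max_lag_s:
                return np.array(lags), np.array(levels)
            lags.append(dd)
            levels.append(level)
        level += 1


def _correlate_chunk(w: np.ndarray, lags, levels, pts_per_level: int):
    """Multi-tau correlation of one binned (weighted) trace."""
    out = np.full(len(lags), np.nan)
    level = 0
    cur = w.astype(np.float64)
    for i, (d, lev) in enumerate(zip(lags, levels)):
        while lev > level:
            m = cur.size - (cur.size % 2)
            cur = cur[:m:2] + cur[1:m:2]
            level += 1
        M = cur.size
        if d >= M:
            continue
        head = cur[: M - d]
        tail = cur[d:]
        s = float(head @ tail)
        w_head = float(head.sum())
        w_tail = float(tail.sum())
        if w_head <= 0 or w_tail <= 0:
            continue
        out[i] = s * (M - d) / (w_head * w_tail) - 1.0
    return out


def correlate(
    photons: PhotonTimeList,
    chunk_s: float = 10.0,
    base_bin_s: float = 1e-6,
    max_lag_s: float = 1.0,
    pts_per_level: int = 8,
    reject_outliers: bool = True,
    t0_s: float | None = None,
) -> CorrelationCurve:
    """Chunked, outlier-rejected correlation of a photon time list.

    The record is split into ``chunk_s`` chunks which are correlated
    independently and averaged; chunks whose count rate or early-lag
    amplitude deviates more than 3 robust sigma from the median are
    rejected (automated stand-in for visual inspection).
    """
    t = photons.times_s
    w = photons.weights if photons.weights is not None else np.ones(t.size)
    if t.size == 0:
        raise ValueError("empty photon list")
    if t0_s is None:
        t0_s = 0.0
    duration = t.max() - t0_s
    # count a trailing chunk as complete if it is filled to >= 99%
    n_chunks = max(int(duration / chunk_s + 0.01), 1)

    lags, levels = multitau_lags(base_bin_s, max_lag_s, pts_per_level)
    tau = lags * base_bin_s * 2.0**levels
    lag_width = base_bin_s * 2.0**levels

    chunk_G = np.full((n_chunks, lags.size), np.nan)
    rates = np.zeros(n_chunks)
    m_bins = int(round(chunk_s / base_bin_s))
    for c in range(n_chunks):
        lo = t0_s + c * chunk_s
        sel = (t >= lo) & (t < lo + chunk_s)
        if not sel.any():
            log.info("chunk %d empty, skipped", c)
            continue
        idx = np.minimum(((t[sel] - lo) / base_bin_s).astype(np.int64), m_bins - 1)
        trace = np.bincount(idx, weights=w[sel], minlength=m_bins)
        chunk_G[c] = _correlate_chunk(trace, lags, levels, pts_per_level)
        rates[c] = w[sel].sum() / chunk_s

    kept = ~np.isnan(chunk_G).all(axis=1)
    if reject_outliers and kept.sum() >= 3:
        amp = np.nanmean(chunk_G[:, : pts_per_level], axis=1)
        for metric in (rates, amp):
            med = np.median(metric[kept])
            mad = np.median(np.abs(metric[kept] - med)) * 1.4826
            if mad > 0:
                kept &= np.abs(metric - med) <= 3 * mad
        if not kept.any():  # never reject everything
            kept = ~np.isnan(chunk_G).all(axis=1)

    G = np.nanmean(chunk_G[kept], axis=0)
    with np.errstate(invalid="ignore"):
        G_sd = np.nanstd(chunk_G[kept], axis=0, ddof=1) if kept.sum() > 1 else np.full_like(G, np.nan)
    return CorrelationCurve(
        tau_s=tau, G=G, G_sd=G_sd, chunk_G=chunk_G, chunk_kept=kept, lag_width_s=lag_width
    )


# ---------------------------------------------------------------------------
# FLCS filters
# ---------------------------------------------------------------------------


@dataclass
class FlcsFilters:
    """Per-dt-bin statistical filters for fluorescence vs background."""

    bin_edges_ns: np.ndarray
    fluor: np.ndarray  # filter values on retained bins (NaN where removed)
    background: np.ndarray
    retained: np.ndarray  # bool per bin inside the crop
    crop: tuple  # (lo_ns, hi_ns)
    amplitude: float
    tau_ns: float
    offset: float

    def photon_weights(self, dt_ns: np.ndarray) -> np.ndarray:
        """Fluorescence-filter weight per photon; 0 outside crop/removed."""
        dt = np.asarray(dt_ns, dtype=float)
        nbins = self.retained.size
        width = self.bin_edges_ns[1] - self.bin_edges_ns[0]
        k = ((dt - self.bin_edges_ns[0]) / width).astype(np.int64)
        ok = (k >= 0) & (k < nbins)
        kk = np.clip(k, 0, nbins - 1)
        wvals = np.where(self.retained, np.nan_to_num(self.fluor), 0.0)
        return np.where(ok, wvals[kk], 0.0)


def flcs_filters(
    dt_ns: np.ndarray,
    laser_period_ns: float,
    bin_width_ns: float = 0.048,
    crop_after_peak_ns: float = 10.0,
) -> FlcsFilters:
    """Build the two FLCS filter functions from a decay histogram.

    The histogram is cropped from its peak to ~10 ns later and fitted with
    ``A exp(-t/tau) + B``.  Bins statistically indistinguishable from the
    offset (counts <= B + 3 sqrt(B)) are removed outright.  The remaining
    bins get weighted-least-squares filters for the two normalized
    patterns {exponential decay, uniform background}; the filters sum to 1
    on every retained bin and give each photon a weight equal to the
    fluorescence filter at its start--stop time.
    """
    centers, counts = decay_histogram(dt_ns, laser_period_ns, bin_width_ns)
    a, tau, b, ok = fit_exp_decay(centers, counts, crop_after_peak_ns)
    k0 = int(np.argmax(counts))
    lo = k0
    hi = min(int(np.ceil((centers[k0] + crop_after_peak_ns) / bin_width_ns)), counts.size)
    c = counts[lo:hi].astype(float)
    t_rel = centers[lo:hi] - centers[k0]
    edges = np.arange(lo, hi + 1) * bin_width_ns

    if not ok or a <= 0:
        log.warning("FLCS decay fit failed; filters disabled (unit weights)")
        return FlcsFilters(
            bin_edges_ns=edges,
            fluor=np.ones(c.size),
            background=np.zeros(c.size),
            retained=np.ones(c.size, dtype=bool),
            crop=(edges[0], edges[-1]),
            amplitude=np.nan,
            tau_ns=np.nan,
            offset=np.nan,
        )

    retained = c > b + 3 * np.sqrt(max(b, 0.0))
    fluor = np.full(c.size, np.nan)
    bg = np.full(c.size, np.nan)
    if b < 1e-3 * a:
        # single-component limit: everything retained is fluorescence
        fluor[retained] = 1.0
        bg[retained] = 0.0
    elif retained.sum() >= 2:
        e = np.exp(-t_rel[retained] / tau)
        model = a * e + b  # expected counts (variance weights)
        # patterns normalized to unit sum -> pointwise partition property
        p1 = e / e.sum()
        p2 = np.full(e.size, 1.0 / e.size)
        m = np.stack([p1, p2])  # (2, nbins)
        wgt = 1.0 / np.maximum(model, 1e-12)
        d = (m * wgt) @ m.T
        filt = np.linalg.solve(d, m * wgt)  # (2, nbins)
        fluor[retained] = filt[0]
        bg[retained] = filt[1]
    return FlcsFilters(
        bin_edges_ns=edges,
        fluor=fluor,
        background=bg,
        retained=retained,
        crop=(edges[0], edges[-1]),
        amplitude=a,
        tau_ns=tau,
        offset=b,
    )


# ---------------------------------------------------------------------------
# FCS model fitting
# ---------------------------------------------------------------------------


@dataclass
class FcsFit:
    N: float
    tau_d_s: float
    omega0_um: float
    k: float
    D_um2_s: float
    concentration_um3: float
    radius_um: float = 0.0
    scan_period_s: float = 0.0
    label: str = ""
    perr: tuple = ()


def point_model(tau, N, tau_d, k):
    """1-component 3D-Gaussian diffusion autocorrelation."""
    x = tau / tau_d
    return (1.0 / N) / (1.0 + x) / np.sqrt(1.0 + x / k**2)


def circular_model(tau, N, tau_d, omega0_um, k, radius_um, scan_period_s):
    """Scanned-focus model: diffusion term times the periodic displacement
    factor exp(-d(tau)^2 / (w0^2 (1 + tau/tau_d))),
    d(tau) = 2 R sin(pi tau / T_scan)."""
    base = point_model(tau, N, tau_d, k)
    if radius_um == 0:
        return base
    d2 = (2.0 * radius_um * np.sin(np.pi * tau / scan_period_s)) ** 2
    return base * np.exp(-d2 / (omega0_um**2 * (1.0 + tau / tau_d)))


def _bin_averaged(model, tau, widths, n_sub: int = 9):
    """Average a model over each lag's cascade bin (triangular kernel)."""
    offs = np.linspace(-1.0, 1.0, n_sub)
    wts = 1.0 - np.abs(offs)
    wts /= wts.sum()
    out = np.zeros_like(tau)
    for o, wt in zip(offs, wts):
        out += wt * model(np.maximum(tau + o * widths, 1e-12))
    return out


def effective_volume_um3(omega0_um: float, k: float) -> float:
    return np.pi**1.5 * omega0_um**3 * k


def _finite(curve: CorrelationCurve, fit_range):
    sel = np.isfinite(curve.G)
    if fit_range is not None:
        sel &= (curve.tau_s >= fit_range[0]) & (curve.tau_s <= fit_range[1])
    return sel


def fit_point_fcs(
    curve: CorrelationCurve,
    omega0_um: float,
    k: float = 4.5,
    fit_range=None,
    label: str = "",
) -> FcsFit:
    """Fit N and tau_D with the focal spot fixed; D = w0^2 / (4 tau_D)."""
    sel = _finite(curve, fit_range)
    tau, g = curve.tau_s[sel], curve.G[sel]
    g0 = max(np.nanmean(g[:4]), 1e-6)
    below = np.flatnonzero(g < g0 / 2)
    tau_d0 = tau[below[0]] if below.size else float(np.median(tau))
    p0 = (1.0 / g0, max(tau_d0, tau[0]))
    popt, pcov = curve_fit(
        lambda t, N, td: point_model(t, N, td, k),
        tau,
        g,
        p0=p0,
        bounds=([1e-6, 1e-9], [np.inf, np.inf]),
        maxfev=20000,
    )
    N, tau_d = popt
    D = omega0_um**2 / (4 * tau_d)
    return FcsFit(
        N=N,
        tau_d_s=tau_d,
        omega0_um=omega0_um,
        k=k,
        D_um2_s=D,
        concentration_um3=N / effective_volume_um3(omega0_um, k),
        label=label,
        perr=tuple(np.sqrt(np.diag(pcov))),
    )


def fit_circular_fcs(
    curve: CorrelationCurve,
    radius_um: float,
    scan_period_s: float,
    k: float = 4.5,
    fit_range=None,
    label: str = "",
) -> FcsFit:
    """Fit N, tau_D and the focal spot size from a circular-scan curve.

    Scan radius and periodicity stay fixed.  The model is averaged over
    each lag's cascade bin so the periodic scanning factor is compared on
    the same footing as the multi-tau estimator.
    """
    sel = _finite(curve, fit_range)
    tau, g = curve.tau_s[sel], curve.G[sel]
    widths = curve.lag_width_s[sel]
    g0 = max(np.nanmean(g[:4]), 1e-6)
    p0 = (1.0 / g0, 1e-3, 0.3)

    def model(t, N, td, w0):
        return _bin_averaged(
            lambda tt: circular_model(tt, N, td, w0, k, radius_um, scan_period_s),
            t,
            widths,
        )

    popt, pcov = curve_fit(
        model,
        tau,
        g,
        p0=p0,
        bounds=([1e-6, 1e-9, 1e-3], [np.inf, np.inf, 10.0]),
        maxfev=20000,
    )
    N, tau_d, w0 = popt
    return FcsFit(
        N=N,
        tau_d_s=tau_d,
        omega0_um=w0,
        k=k,
        D_um2_s=w0**2 / (4 * tau_d),
        concentration_um3=N / effective_volume_um3(w0, k),
        radius_um=radius_um,
        scan_period_s=scan_period_s,
        label=label,
        perr=tuple(np.sqrt(np.diag(pcov))),
    )


# ---------------------------------------------------------------------------
# spot variation / diffusion law
# ---------------------------------------------------------------------------


@dataclass
class SpotVariationResult:
    omega0_sq_um2: np.ndarray
    tau_d_s: np.ndarray
    slope_s_per_um2: float  # 1 / (4 D)
    intercept_s: float
    intercept_se_s: float
    D_per_class: dict
    D_from_slope_um2_s: float
    ratio_central_to_largest: float
    concentration_um3: dict


def spot_variation(fits: dict) -> SpotVariationResult:
    """Diffusion-law summary from per-detection-volume FCS fits.

    Linear fit of tau_D versus w0^2; free diffusion shows a straight line
    through the origin with slope 1/(4D).
    """
    if len(fits) < 2:
        raise ValueError("need at least two detection-volume classes")
    labels = list(fits)
    w2 = np.array([fits[l].omega0_um**2 for l in labels])
    td = np.array([fits[l].tau_d_s for l in labels])
    order = np.argsort(w2)
    w2, td = w2[order], td[order]
    if len(w2) > 2:
        coef, cov = np.polyfit(w2, td, 1, cov=True)
    else:
        coef, cov = np.polyfit(w2, td, 1), None
    slope, intercept = float(coef[0]), float(coef[1])
    se = float(np.sqrt(cov[1, 1])) if cov is not None else np.nan
    d_per = {l: fits[l].D_um2_s for l in labels}
    central = min(labels, key=lambda l: fits[l].omega0_um)
    largest = max(labels, key=lambda l: fits[l].omega0_um)
    return SpotVariationResult(
        omega0_sq_um2=w2,
        tau_d_s=td,
        slope_s_per_um2=slope,
        intercept_s=intercept,
        intercept_se_s=se,
        D_per_class=d_per,
        D_from_slope_um2_s=1.0 / (4.0 * slope) if slope > 0 else np.nan,
        ratio_central_to_largest=d_per[central] / d_per[largest],
        concentration_um3={l: fits[l].concentration_um3 for l in labels},
    )


def lifetime_vs_time(
    lists_by_class: dict,
    window_s: float,
    omega0_by_class: dict,
    k_by_class: dict,
    laser_period_ns: float = 25.0,
    bin_width_ns: float = 0.048,
    min_photons: int = 1000,
    base_bin_s: float = 1e-6,
    max_lag_s: float = 0.1,
):
    """Per-window lifetime and diffusion-ratio time series.

    For each window of ``window_s``: fit the decay histogram of the largest
    class for tau_fl, fit point FCS per class, and report
    D_smallest / D_largest.  Windows with fewer than ``min_photons``
    photons are masked.
    """
    largest = max(lists_by_class, key=lambda l: omega0_by_class[l])
    smallest = min(lists_by_class, key=lambda l: omega0_by_class[l])
    t_end = max(pl.times_s.max() for pl in lists_by_class.values())
    n_win = int(t_end / window_s)
    t_mid = (np.arange(n_win) + 0.5) * window_s
    tau_fl = np.full(n_win, np.nan)
    ratio = np.full(n_win, np.nan)
    mask = np.zeros(n_win, dtype=bool)
    for wdx in range(n_win):
        lo, hi = wdx * window_s, (wdx + 1) * window_s
        big = lists_by_class[largest]
        sel = (big.times_s >= lo) & (big.times_s < hi)
        if sel.sum() < min_photons:
            continue
        centers, counts = decay_histogram(big.dt_ns[sel], laser_period_ns, bin_width_ns)
        _, tau, _, ok = fit_exp_decay(centers, counts)
        if not ok:
            continue
        tau_fl[wdx] = tau
        mask[wdx] = True
        d = {}
        try:
            for lbl, pl in lists_by_class.items():
                s = (pl.times_s >= lo) & (pl.times_s < hi)
                sub = PhotonTimeList(times_s=pl.times_s[s] - lo, label=lbl)
                curve = correlate(
                    sub,
                    chunk_s=window_s,
                    base_bin_s=base_bin_s,
                    max_lag_s=max_lag_s,
                    reject_outliers=False,
                )
                fit = fit_point_fcs(curve, omega0_by_class[lbl], k_by_class[lbl])
                d[lbl] = fit.D_um2_s
            ratio[wdx] = d[smallest] / d[largest]
        except RuntimeError:
            continue
    return {"t_s": t_mid, "tau_fl_ns": tau_fl, "d_ratio": ratio, "mask": mask}
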