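"""Shared decay-fitting helpers."""

from __future__ import annotations

import numpy as np
from scipy.optimize import curve_fit


def _exp_offset(t, a, tau, b):
    return a * np.exp(-t / tau) + b


def fit_exp_decay(
    centers_ns: np.ndarray,
    counts: np.ndarray,
    fit_window_ns: float = 10.0,
):
    """Fit ``A exp(-t/tau) + B`` on the post-peak range of a histogram.

    The fit range runs from the histogram peak to ``fit_window_ns`` later.
    Returns ``(A, tau_ns, B, ok)`` with times re-referenced to the peak.
    """
    counts = np.asarray(counts, dtype=float)
    centers = np.asarray(centers_ns, dtype=float)
    k0 = int(np.argmax(counts))
    sel = (centers >= centers[k0]) & (centers <= centers[k0] + fit_window_ns)
    t = centers[sel] - centers[k0]
    c = counts[sel]
    if c.sum() <= 0 or t.size < 4:
        return np.nan, np.nan, np.nan, False
    b0 = max(float(c.min()), 0.0)
    a0 = max(float(c[0] - b0), 1.0)
    # crude log-slope seed on the upper half of the decay
    upper = c > b0 + 0.25 * a0
    if upper.sum() >= 2:
        slope = np.polyfit(t[upper], np.log(np.maximum(c[upper] - b0, 1e-9)), 1)[0]
        tau0 = -1.0 / slope if slope < 0 else 2.0
    else:
        tau0 = 2.0
    tau0 = float(np.clip(tau0, 0.05, 50.0))
    try:
        popt, _ = curve_fit(
            _exp_offset,
            t,
            c,
            p0=(a0, tau0, b0),
            sigma=np.sqrt(np.maximum(c, 1.0)),
            bounds=([0, 1e-3, 0], [np.inf, 1e3, np.inf]),
            maxfev=20000,
        )
        return float(popt[0]), float(popt[1]), float(popt[2]), True
    except (RuntimeError, ValueError):
        return a0, tau0, b0, False


def fit_folded_decay(
    centers_ns: np.ndarray,
    counts: np.ndarray,
    period_ns: float,
    peak_exclusion_ns: float = 0.6,
):
    """Fit ``A exp(-((t - t0) mod period)/tau) + B`` over the full period.

    The pre-peak region (wrapped tail + background) pins the uniform
    offset much better than a post-peak crop.  Bins within
    ``peak_exclusion_ns`` of the peak are excluded so an instrument
    response of up to a few hundred ps does not distort the IRF-free
    model.  Returns ``(A, tau_ns, t0_ns, B, ok)``.
    """
    counts = np.asarray(counts, dtype=float)
    centers = np.asarray(centers_ns, dtype=float)
    k0 = int(np.argmax(counts))
    a_post, tau_post, b_post, _ = fit_exp_decay(centers, counts, fit_window_ns=period_ns / 2)
    half = period_ns / 2
    dist = np.abs(np.mod(centers - centers[k0] + half, period_ns) - half)
    sel = dist > peak_exclusion_ns

    def model(t, a, tau, t0, b):
        return a * np.exp(-np.mod(t - t0, period_ns) / tau) + b

    try:
        popt, _ = curve_fit(
            model,
            centers[sel],
            counts[sel],
            p0=(a_post, tau_post, centers[k0], b_post),
            sigma=np.sqrt(np.maximum(counts[sel], 1.0)),
            bounds=([0, 1e-3, -period_ns, 0], [np.inf, 1e3, 2 * period_ns, np.inf]),
            maxfev=20000,
        )
        return float(popt[0]), float(popt[1]), float(popt[2]), float(popt[3]), True
    except (RuntimeError, ValueError):
        return a_post, tau_post, float(centers[k0]), b_post, False


def decay_histogram(dt_ns: np.ndarray, laser_period_ns: float, bin_width_ns: float = 0.048):
    """Left-edge-binned TCSPC histogram over [0, laser_period)."""
    n_bins = int(np.ceil(laser_period_ns / bin_width_ns))
    dt = np.mod(np.asarray(dt_ns, dtype=float), laser_period_ns)
    counts = np.bincount(
        np.minimum((dt / bin_width_ns).astype(np.int64), n_bins - 1), minlength=n_bins
    )
    centers = (np.arange(n_bins) + 0.5) * bin_width_ns
    return centers, counts
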