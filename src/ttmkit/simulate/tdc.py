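"""Tapped-delay-line model and the event -> (coarse count, tap code) encoder.

Timing convention
-----------------
For an event at time ``t`` (ns, continuous), the coarse counter value
recorded for it is ``n = floor(t / T) + 1`` — the value the free-running
counter holds at the first rising edge *after* the event.  The fine value
interpolated by the delay line is the elapsed time since the previous
rising edge, ``f = t - (n - 1) * T``, so that ``t = (n - 1) * T + f``.
With this convention the start--stop time of a photon against the next
SYNC is exactly ``dt_stop - dt_start + (n_sync - n_photon) * T``, which is
the reconstruction formula used downstream.

The tap code is the index of the tap interval containing ``f``; codes
saturate at the last tap (thermometer overflow).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ..constants import LSB_PS, N_CHANNELS_DEFAULT, T_SYSCLK_NS


@dataclass
class TdlModel:
    """Per-line tap widths (ns) for the START lines and the shared STOP line.

    Invariant: every line is at least as long as the clock period.
    """

    start_widths: np.ndarray  # (n_channels, n_taps)
    stop_widths: np.ndarray  # (n_taps,)
    clock_period: float = T_SYSCLK_NS

    def __post_init__(self) -> None:
        self.start_widths = np.atleast_2d(np.asarray(self.start_widths, dtype=float))
        self.stop_widths = np.asarray(self.stop_widths, dtype=float)
        if (self.start_widths <= 0).any() or (self.stop_widths <= 0).any():
            raise ValueError("tap widths must be positive")
        if self.start_widths.sum(axis=1).min() < self.clock_period or (
            self.stop_widths.sum() < self.clock_period
        ):
            raise ValueError("delay line shorter than the clock period")

    @property
    def n_channels(self) -> int:
        return self.start_widths.shape[0]

    @property
    def n_taps(self) -> int:
        return self.start_widths.shape[1]

    @classmethod
    def ideal(
        cls,
        n_channels: int = N_CHANNELS_DEFAULT,
        n_taps: int = 87,
        lsb_ps: float = LSB_PS,
        clock_period: float = T_SYSCLK_NS,
    ) -> "TdlModel":
        """Uniform taps; 87 x 48 ps covers 4.176 ns > one clock period."""
        w = np.full(n_taps, lsb_ps * 1e-3)
        return cls(np.tile(w, (n_channels, 1)), w.copy(), clock_period)

    @classmethod
    def dispersed(
        cls,
        seed: int,
        sigma_frac: float = 0.05,
        n_channels: int = N_CHANNELS_DEFAULT,
        n_taps: int = 90,
        lsb_ps: float = LSB_PS,
        clock_period: float = T_SYSCLK_NS,
    ) -> "TdlModel":
        """Log-normally dispersed tap widths around the nominal LSB.

        Uses a slightly longer line (90 taps) so the dispersed sum stays
        safely above the clock period.
        """
        rng = np.random.default_rng(seed)
        mu = np.log(lsb_ps * 1e-3)
        sig = np.sqrt(np.log(1 + sigma_frac**2))
        start = rng.lognormal(mu - sig**2 / 2, sig, size=(n_channels, n_taps))
        stop = rng.lognormal(mu - sig**2 / 2, sig, size=n_taps)
        return cls(start, stop, clock_period)


def _encode_line(times_ns: np.ndarray, widths: np.ndarray, clock_period: float):
    """Encode events on one delay line.  Returns (n, code, kept_mask)."""
    t = np.asarray(times_ns, dtype=float)
    order = np.argsort(t, kind="stable")
    t_sorted = t[order]
    traversal = widths.sum()
    # dead time: drop events within one line traversal of the previously
    # *accepted* event on this line
    kept_sorted = np.ones(t_sorted.size, dtype=bool)
    if t_sorted.size:
        last = -np.inf
        gaps_ok = np.diff(t_sorted, prepend=-np.inf) >= traversal
        if gaps_ok.all():
            pass  # fast path: no conflicts at all
        else:
            for i, ti in enumerate(t_sorted):
                if ti - last < traversal:
                    kept_sorted[i] = False
                else:
                    last = ti
    kept = np.empty_like(kept_sorted)
    kept[order] = kept_sorted

    n = np.floor(t / clock_period).astype(np.int64) + 1
    fine = t - (n - 1) * clock_period
    edges = np.concatenate(([0.0], np.cumsum(widths)))
    code = np.searchsorted(edges, fine, side="right") - 1
    code = np.clip(code, 0, widths.size - 1)
    return n, code.astype(np.int64), kept


def tdc_encode(event_times_ns: np.ndarray, widths: np.ndarray, clock_period: float = T_SYSCLK_NS):
    """Quantize asynchronous event times on a single delay line.

    Returns ``(n, code, kept)`` where ``n`` is the coarse count at the next
    rising edge, ``code`` the tap index and ``kept`` the dead-time survival
    mask (dropped events keep placeholder codes).
    """
    return _encode_line(np.asarray(event_times_ns, float), np.asarray(widths, float), clock_period)


def tdc_encode_channels(
    times_ns: np.ndarray, channels: np.ndarray, tdl: TdlModel
):
    """Encode photon events through their per-channel START lines.

    Returns ``(n, code, kept)`` aligned with the inputs.
    """
    times_ns = np.asarray(times_ns, float)
    channels = np.asarray(channels)
    n = np.empty(times_ns.size, dtype=np.int64)
    code = np.empty(times_ns.size, dtype=np.int64)
    kept = np.empty(times_ns.size, dtype=bool)
    for ch in np.unique(channels):
        sel = channels == ch
        n[sel], code[sel], kept[sel] = _encode_line(
            times_ns[sel], tdl.start_widths[int(ch)], tdl.clock_period
        )
    return n, code, kept
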