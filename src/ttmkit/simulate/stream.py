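"""Assemble simulated events into an on-the-wire word stream.

Implements the event filter: frames are emitted for photon STARTs, for the
first SYNC STOP following a photon, for REF events, and as force-writes at
least once per 1/16 of the counter rollover.  Any emitted frame whose
coarse window also contains a SYNC carries the latched SYNC code and the
"laser data valid" flag, mirroring the hardware latch behaviour.
"""

from __future__ import annotations

import numpy as np

from ..constants import FORCE_WRITE_CYCLES
from ..words import FrameArray, encode_frames
from .tdc import TdlModel, tdc_encode_channels


def _sync_in_window(frame_n, laser_period_ns, sync_phase_ns, clock_period, t_max_ns):
    """Latched SYNC time per coarse window ((n-1)T, nT], NaN if none."""
    hi = frame_n * clock_period
    k = np.floor((hi - sync_phase_ns) / laser_period_ns)
    t_sync = sync_phase_ns + k * laser_period_ns
    ok = (t_sync > hi - clock_period) & (k >= 0) & (t_sync <= t_max_ns)
    return np.where(ok, t_sync, np.nan)


def build_stream(
    photon_times_ns,
    photon_channels,
    tdl: TdlModel,
    laser_period_ns: float,
    sync_phase_ns: float = 0.0,
    ref_pixel_ns=(),
    ref_line_ns=(),
    ref_frame_ns=(),
    duration_ns: float | None = None,
    force_write_cycles: int = FORCE_WRITE_CYCLES,
):
    """Return ``(words, frames, info)`` for the given event series.

    ``info`` holds the photon dead-time survival mask (``kept``), the true
    coarse counts and codes of surviving photons, and drop counters.
    """
    T = tdl.clock_period
    t_ph = np.asarray(photon_times_ns, dtype=float)
    ch_ph = np.asarray(photon_channels, dtype=np.int64)
    if duration_ns is None:
        duration_ns = float(t_ph.max()) + laser_period_ns if t_ph.size else laser_period_ns

    n_p, code_p, kept = tdc_encode_channels(t_ph, ch_ph, tdl)
    tk, chk = t_ph[kept], ch_ph[kept]
    n_pk, code_pk = n_p[kept], code_p[kept]

    # the STOP transmitted for each photon: first SYNC strictly after it
    k_next = np.floor((tk - sync_phase_ns) / laser_period_ns) + 1
    t_stop = sync_phase_ns + k_next * laser_period_ns
    n_stop = np.floor(t_stop / T).astype(np.int64) + 1

    n_ref_px = np.floor(np.asarray(ref_pixel_ns, float) / T).astype(np.int64) + 1
    n_ref_ln = np.floor(np.asarray(ref_line_ns, float) / T).astype(np.int64) + 1
    n_ref_fr = np.floor(np.asarray(ref_frame_ns, float) / T).astype(np.int64) + 1

    n_end = int(np.floor(duration_ns / T)) + 1
    n_fw = np.arange(1, n_end + 1, force_write_cycles, dtype=np.int64)

    frame_n = np.unique(
        np.concatenate([n_pk, n_stop, n_ref_px, n_ref_ln, n_ref_fr, n_fw, [n_end]])
    )

    t_sync_latched = _sync_in_window(frame_n, laser_period_ns, sync_phase_ns, T, duration_ns)
    sync_valid = ~np.isnan(t_sync_latched)
    stop_code = np.zeros(frame_n.size, dtype=np.int64)
    if sync_valid.any():
        ts = t_sync_latched[sync_valid]
        fine = ts - np.floor(ts / T) * T
        edges = np.concatenate(([0.0], np.cumsum(tdl.stop_widths)))
        sc = np.searchsorted(edges, fine, side="right") - 1
        stop_code[sync_valid] = np.clip(sc, 0, tdl.stop_widths.size - 1)

    hit_frame = np.searchsorted(frame_n, n_pk)
    order = np.lexsort((chk, hit_frame))

    frames = FrameArray(
        step=(frame_n % (1 << 16)).astype(np.uint16),
        stop_code=stop_code.astype(np.uint8),
        sync_valid=sync_valid,
        ref_pixel=np.isin(frame_n, n_ref_px),
        ref_line=np.isin(frame_n, n_ref_ln),
        ref_frame=np.isin(frame_n, n_ref_fr),
        spare=np.zeros(frame_n.size, dtype=np.uint8),
        hit_frame=hit_frame[order].astype(np.int64),
        hit_channel=chk[order].astype(np.uint8),
        hit_code=code_pk[order].astype(np.uint8),
        hit_valid=np.ones(order.size, dtype=bool),
    )
    words = encode_frames(frames, n_channels=tdl.n_channels)
    info = {
        "kept": kept,
        "n_dropped_dead_time": int((~kept).sum()),
        "photon_n": n_pk,
        "photon_code": code_pk,
        "photon_channel": chk,
        "stop_n": n_stop,
        "n_frames": frame_n.size,
    }
    return words, frames, info
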