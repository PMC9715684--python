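"""Pre-processing: decoded frames -> joinable event tables.

The main table holds one row per SYNC event (monotonic counter, STOP code,
scan coordinates, unique row index ``idx``); each channel table holds one
row per photon with its START code, the elapsed-cycle count ``dn`` to its
associated SYNC, and the ``idx`` join key.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import h5py
import numpy as np

from .constants import COUNTER_ROLLOVER, FORCE_WRITE_CYCLES, N_CHANNELS_DEFAULT, T_SYSCLK_NS
from .words import FrameArray

log = logging.getLogger(__name__)

SCHEMA_VERSION = 1

MAIN_DTYPE = np.dtype(
    [
        ("idx", "i8"),
        ("n_sync", "i8"),
        ("stop_code", "u1"),
        ("x", "i4"),
        ("y", "i4"),
        ("fr", "i4"),
    ]
)
CHANNEL_DTYPE = np.dtype([("idx", "i8"), ("dn", "i8"), ("start_code", "u1")])
MAIN_CAL_DTYPE = np.dtype(MAIN_DTYPE.descr + [("t_sync_ns", "f8")])
CHANNEL_CAL_DTYPE = np.dtype(CHANNEL_DTYPE.descr + [("dt_ns", "f8")])


class SchemaError(RuntimeError):
    """HDF5 layout does not match the expected schema version."""


@dataclass
class EventTables:
    """Main SYNC table plus per-channel photon tables."""

    main: np.ndarray
    channels: list  # list of structured arrays, one per photon channel
    t_sysclk_ns: float = T_SYSCLK_NS
    laser_period_ns: float = 25.0
    discarded_photons: int = 0
    calibrated: bool = False
    attrs: dict = field(default_factory=dict)

    @property
    def n_channels(self) -> int:
        return len(self.channels)

    @property
    def n_photons(self) -> int:
        return int(sum(len(c) for c in self.channels))


def unwrap_counter(step: np.ndarray, counter_bits_rollover: int = COUNTER_ROLLOVER) -> np.ndarray:
    """Make the wrapped 16-bit STEP values monotonic.

    Whenever a value decreases, one rollover is added to it and to all
    following values.  Warns when a jump larger than twice the force-write
    interval appears, which indicates upstream data loss.
    """
    step = np.asarray(step, dtype=np.int64)
    if step.size == 0:
        return step.copy()
    wraps = np.cumsum(np.diff(step, prepend=step[0]) < 0)
    n = step + wraps * counter_bits_rollover
    if np.diff(n).size and np.diff(n).max() > 2 * FORCE_WRITE_CYCLES:
        warnings.warn(
            "counter gap exceeds two force-write intervals; possible data loss",
            stacklevel=2,
        )
    return n


def assign_coordinates(ref_pixel, ref_line, ref_frame):
    """Scan coordinates per frame from pixel/line/frame clock flags.

    Counters start at -1 so the first clock of each kind addresses index 0.
    A pixel event increments x; a line event resets x and increments y; a
    frame event resets x and y and increments fr.  Events within one frame
    apply in the order frame, line, pixel.  Positions reset by a line or
    frame event report the next pixel (x = 0) once scanning has started.
    """
    ref_pixel = np.asarray(ref_pixel, bool)
    ref_line = np.asarray(ref_line, bool)
    ref_frame = np.asarray(ref_frame, bool)
    n = ref_pixel.size
    idx = np.arange(n)
    p_cum = np.cumsum(ref_pixel)
    l_cum = np.cumsum(ref_line)
    f_cum = np.cumsum(ref_frame)

    last_f = np.maximum.accumulate(np.where(ref_frame, idx, -1))
    last_l = np.maximum.accumulate(np.where(ref_line, idx, -1))
    last_reset_x = np.maximum(last_f, last_l)

    fr = f_cum - 1

    y = l_cum - 1
    has_f = last_f >= 0
    j = np.maximum(last_f, 0)
    y = np.where(has_f, l_cum - l_cum[j] + ref_line[j] - 1, y)

    x = p_cum - 1
    has_r = last_reset_x >= 0
    r = np.maximum(last_reset_x, 0)
    x = np.where(has_r, p_cum - p_cum[r] + ref_pixel[r] - 1, x)

    # photons stranded between a line/frame event and the next pixel clock
    # belong to the upcoming pixel once scanning has started
    x = np.where((x == -1) & (p_cum > 0), 0, x)
    y = np.where((y == -1) & (l_cum > 0), 0, y)
    return x.astype(np.int32), y.astype(np.int32), fr.astype(np.int32)


def match_start_stop(
    frames: FrameArray,
    n_channels: int = N_CHANNELS_DEFAULT,
    laser_period_ns: float = 25.0,
    max_dn: int | None = None,
    t_sysclk_ns: float = T_SYSCLK_NS,
) -> EventTables:
    """Reverse start--stop association of photons to their next SYNC.

    Each photon is linked to the first SYNC at or after its own coarse
    window; a same-window SYNC whose STOP code is below the photon's START
    code happened *before* the photon and is skipped.  Photons with no SYNC
    within ``max_dn`` cycles (default: two laser periods) are discarded and
    counted.
    """
    if max_dn is None:
        max_dn = int(np.ceil(2 * laser_period_ns / t_sysclk_ns))
    n = unwrap_counter(frames.step)
    x, y, fr = assign_coordinates(frames.ref_pixel, frames.ref_line, frames.ref_frame)

    sync_sel = np.flatnonzero(frames.sync_valid)
    n_sync = n[sync_sel]
    main = np.empty(sync_sel.size, dtype=MAIN_DTYPE)
    main["idx"] = np.arange(sync_sel.size)
    main["n_sync"] = n_sync
    main["stop_code"] = frames.stop_code[sync_sel]
    main["x"] = x[sync_sel]
    main["y"] = y[sync_sel]
    main["fr"] = fr[sync_sel]

    valid_hits = frames.hit_valid
    hit_frame = frames.hit_frame[valid_hits]
    hit_channel = frames.hit_channel[valid_hits]
    hit_code = frames.hit_code[valid_hits].astype(np.int64)
    n_photon = n[hit_frame]

    j = np.searchsorted(n_sync, n_photon, side="left")
    if n_sync.size:
        # same-window SYNC that precedes the photon: STOP code below START code
        in_range = j < n_sync.size
        jj = np.minimum(j, n_sync.size - 1)
        same = in_range & (n_sync[jj] == n_photon)
        before = same & (frames.stop_code[sync_sel[jj]].astype(np.int64) < hit_code)
        j = j + before.astype(np.int64)

    ok = j < n_sync.size
    if n_sync.size:
        dn = np.where(ok, n_sync[np.minimum(j, n_sync.size - 1)] - n_photon, -1)
    else:
        dn = np.full(n_photon.size, -1, dtype=np.int64)
    ok &= (dn >= 0) & (dn <= max_dn)
    discarded = int((~ok).sum())
    if discarded:
        log.info("discarded %d photons with no SYNC within %d cycles", discarded, max_dn)

    channels = []
    for ch in range(n_channels):
        sel = (hit_channel == ch) & ok
        rows = np.empty(int(sel.sum()), dtype=CHANNEL_DTYPE)
        rows["idx"] = j[sel]
        rows["dn"] = dn[sel]
        rows["start_code"] = hit_code[sel]
        channels.append(rows)

    return EventTables(
        main=main,
        channels=channels,
        t_sysclk_ns=t_sysclk_ns,
        laser_period_ns=laser_period_ns,
        discarded_photons=discarded,
    )


def calibrate_tables(tables: EventTables, calib, flip_to_excitation: bool = True) -> EventTables:
    """Attach calibrated times to the tables.

    Adds ``t_sync_ns = n_sync * T + dt_sync`` to the main table and the
    start--stop time ``dt_ns`` to every channel table.  The raw
    reconstruction measures photon -> next SYNC; with
    ``flip_to_excitation`` (default) it is folded into the delay from the
    *preceding* pulse, which is the axis decay histograms are read on.
    """
    from .calibrate import start_stop  # local import to avoid cycles

    T = tables.t_sysclk_ns
    period = tables.laser_period_ns
    main = np.empty(tables.main.size, dtype=MAIN_CAL_DTYPE)
    for name in MAIN_DTYPE.names:
        main[name] = tables.main[name]
    dt_sync = calib.stop_time(tables.main["stop_code"])
    main["t_sync_ns"] = tables.main["n_sync"] * T + dt_sync

    channels = []
    for ch, rows in enumerate(tables.channels):
        out = np.empty(rows.size, dtype=CHANNEL_CAL_DTYPE)
        for name in CHANNEL_DTYPE.names:
            out[name] = rows[name]
        dt_stop = calib.stop_time(tables.main["stop_code"][rows["idx"]])
        dt_start = calib.start_time(ch, rows["start_code"])
        # a channel delay shifts the photon later, shortening the raw
        # photon->SYNC interval; add it back before folding
        raw = start_stop(dt_start, dt_stop, rows["dn"], T) + calib.offsets_ns[ch]
        out["dt_ns"] = np.mod(-raw, period) if flip_to_excitation else raw
        channels.append(out)

    return EventTables(
        main=main,
        channels=channels,
        t_sysclk_ns=T,
        laser_period_ns=period,
        discarded_photons=tables.discarded_photons,
        calibrated=True,
        attrs=dict(tables.attrs),
    )


def write_tables(path, tables: EventTables, compression: str | None = None) -> None:
    """Persist tables to a single HDF5 file (`/main`, `/ch00` ... )."""
    with h5py.File(path, "w") as f:
        f.attrs["schema_version"] = SCHEMA_VERSION
        f.attrs["t_sysclk_ns"] = tables.t_sysclk_ns
        f.attrs["laser_period_ns"] = tables.laser_period_ns
        f.attrs["discarded_photons"] = tables.discarded_photons
        f.attrs["calibrated"] = tables.calibrated
        for k, v in tables.attrs.items():
            f.attrs[k] = v
        f.create_dataset("main", data=tables.main, compression=compression)
        for ch, rows in enumerate(tables.channels):
            f.create_dataset(f"ch{ch:02d}", data=rows, compression=compression)


def read_tables(path) -> EventTables:
    """Read tables back; raises :class:`SchemaError` on layout mismatch."""
    with h5py.File(path, "r") as f:
        version = f.attrs.get("schema_version")
        if version != SCHEMA_VERSION:
            raise SchemaError(f"expected schema version {SCHEMA_VERSION}, found {version}")
        reserved = {"schema_version", "t_sysclk_ns", "laser_period_ns",
                    "discarded_photons", "calibrated"}
        channels = []
        ch = 0
        while f"ch{ch:02d}" in f:
            channels.append(f[f"ch{ch:02d}"][()])
            ch += 1
        return EventTables(
            main=f["main"][()],
            channels=channels,
            t_sysclk_ns=float(f.attrs["t_sysclk_ns"]),
            laser_period_ns=float(f.attrs["laser_period_ns"]),
            discarded_photons=int(f.attrs["discarded_photons"]),
            calibrated=bool(f.attrs["calibrated"]),
            attrs={k: f.attrs[k] for k in f.attrs if k not in reserved},
        )
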