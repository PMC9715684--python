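"""Bit-exact encoder/decoder for the 16-bit word stream.

Every word packs a 7-bit identifier, a 1-bit valid flag and an 8-bit
payload::

    bit 15..9   id
    bit 8       valid
    bit 7..0    payload

A frame (one 240 MHz window) serializes to a fixed 5-word header followed
by one word per channel hit (zero suppression: silent channels emit
nothing).  Header layout, word by word:

    id 123  valid=1        payload bit0..2 = pixel/line/frame REF flags,
                           bit3 = sync_valid (VL), bits 4..7 = 0
    id 124  valid=VL       payload = SYNC tap code (stop_code)
    id 125  valid=1        payload = STEP low byte
    id 126  valid=1        payload = STEP high byte
    id 127  valid=1        payload = spare byte

Channel-data words use id = channel index (< number of photon channels),
valid = hit valid flag, payload = START tap code.

Stream files (``.ttm``) are a 4-byte preamble ``b"TTM1"`` (magic + format
version) followed by the words as little-endian uint16.
"""

from __future__ import annotations

import enum
import logging
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Iterator, Sequence

import numpy as np

from .constants import (
    FORCE_WRITE_CYCLES,
    HEADER_IDS,
    N_CHANNELS_DEFAULT,
    N_HEADER_WORDS,
)

log = logging.getLogger(__name__)

STREAM_MAGIC = b"TTM1"

_ID_REF = 123
_ID_STOP = 124
_ID_STEP_LO = 125
_ID_STEP_HI = 126
_ID_SPARE = 127


class EncodingError(ValueError):
    """A field does not fit its allotted bit range."""


@dataclass(frozen=True)
class DataWord:
    """One 16-bit transfer word: 7-bit id, 1-bit valid flag, 8-bit payload."""

    id: int
    valid: bool
    payload: int

    def pack(self) -> int:
        _check_range("id", self.id, 0x7F)
        _check_range("payload", self.payload, 0xFF)
        return (self.id << 9) | (int(self.valid) << 8) | self.payload

    @classmethod
    def unpack(cls, raw: int) -> "DataWord":
        return cls(id=(raw >> 9) & 0x7F, valid=bool((raw >> 8) & 1), payload=raw & 0xFF)


class TransmitReason(enum.Enum):
    """Why a frame was put on the wire (the four event-filter conditions)."""

    photon_start = "photon_start"
    stop_after_start = "stop_after_start"
    ref_event = "ref_event"
    force_write = "force_write"


@dataclass
class FrameStructure:
    """Content of one coarse-clock window as carried by a frame structure.

    ``hits`` maps channel index -> (start_code, valid).
    """

    step: int = 0
    stop_code: int = 0
    sync_valid: bool = False
    ref_pixel: bool = False
    ref_line: bool = False
    ref_frame: bool = False
    spare: int = 0
    hits: dict = field(default_factory=dict)

    @property
    def ref_flags(self) -> tuple:
        return (self.ref_pixel, self.ref_line, self.ref_frame)

    def __eq__(self, other) -> bool:  # order-insensitive hit comparison
        if not isinstance(other, FrameStructure):
            return NotImplemented
        return (
            self.step == other.step
            and self.stop_code == other.stop_code
            and self.sync_valid == other.sync_valid
            and self.ref_flags == other.ref_flags
            and self.spare == other.spare
            and dict(self.hits) == dict(other.hits)
        )


def _check_range(name: str, value: int, maximum: int) -> None:
    if not 0 <= int(value) <= maximum:
        raise EncodingError(f"{name}={value} out of range [0, {maximum}]")


def encode_frame(frame: FrameStructure, n_channels: int = N_CHANNELS_DEFAULT) -> list:
    """Serialize a frame to its 5 header words plus one word per hit.

    Hits are emitted in ascending channel order.  Raises
    :class:`EncodingError` if any field exceeds its bit range or a channel
    index is not below ``n_channels``.
    """
    _check_range("step", frame.step, 0xFFFF)
    _check_range("stop_code", frame.stop_code, 0xFF)
    _check_range("spare", frame.spare, 0xFF)
    flags = (
        int(frame.ref_pixel)
        | (int(frame.ref_line) << 1)
        | (int(frame.ref_frame) << 2)
        | (int(frame.sync_valid) << 3)
    )
    words = [
        DataWord(_ID_REF, True, flags),
        DataWord(_ID_STOP, bool(frame.sync_valid), frame.stop_code),
        DataWord(_ID_STEP_LO, True, frame.step & 0xFF),
        DataWord(_ID_STEP_HI, True, (frame.step >> 8) & 0xFF),
        DataWord(_ID_SPARE, True, frame.spare),
    ]
    for ch in sorted(frame.hits):
        code, valid = frame.hits[ch]
        if not 0 <= ch < n_channels:
            raise EncodingError(f"channel {ch} not below n_channels={n_channels}")
        _check_range(f"start_code[ch{ch}]", code, 0xFF)
        words.append(DataWord(ch, bool(valid), code))
    return words


@dataclass
class DecodeStats:
    """Bookkeeping of a decode pass."""

    frames: int = 0
    corrupt_frames: int = 0
    discarded_words: int = 0


def decode_stream(
    words: Sequence,
    n_channels: int = N_CHANNELS_DEFAULT,
    stats: DecodeStats | None = None,
) -> Iterator[FrameStructure]:
    """Decode a word sequence back into frames, in stream order.

    Frames whose header ids are out of order or missing are dropped and
    counted in ``stats`` (skip-and-count policy); a truncated trailing frame
    raises a warning and is dropped.
    """
    if stats is None:
        stats = DecodeStats()
    i, n = 0, len(words)
    while i < n:
        w = words[i]
        if w.id != _ID_REF:
            stats.discarded_words += 1
            i += 1
            continue
        if i + N_HEADER_WORDS > n:
            warnings.warn("truncated final frame dropped", stacklevel=2)
            stats.corrupt_frames += 1
            stats.discarded_words += n - i
            break
        header = words[i : i + N_HEADER_WORDS]
        if tuple(h.id for h in header) != HEADER_IDS:
            # broken header: resync on the next id-123 word
            stats.corrupt_frames += 1
            j = i + 1
            while j < n and words[j].id != _ID_REF:
                j += 1
            stats.discarded_words += j - i
            i = j
            continue
        flags = header[0].payload
        frame = FrameStructure(
            step=header[2].payload | (header[3].payload << 8),
            stop_code=header[1].payload,
            sync_valid=bool(flags & 0x8),
            ref_pixel=bool(flags & 0x1),
            ref_line=bool(flags & 0x2),
            ref_frame=bool(flags & 0x4),
            spare=header[4].payload,
        )
        i += N_HEADER_WORDS
        while i < n and words[i].id < n_channels:
            frame.hits[words[i].id] = (words[i].payload, words[i].valid)
            i += 1
        stats.frames += 1
        yield frame


def transmit_decision(
    frame: FrameStructure,
    elapsed_cycles: int,
    pending_start: bool = False,
    force_write_cycles: int = FORCE_WRITE_CYCLES,
):
    """Event-filter decision for one frame.

    Returns the :class:`TransmitReason` that justifies emission, or ``None``
    when the frame is suppressed.  ``elapsed_cycles`` counts coarse cycles
    since the last emitted frame; ``pending_start`` indicates a photon still
    awaiting its SYNC association.
    """
    if any(valid for _, valid in frame.hits.values()):
        return TransmitReason.photon_start
    if frame.sync_valid and pending_start:
        return TransmitReason.stop_after_start
    if frame.ref_pixel or frame.ref_line or frame.ref_frame:
        return TransmitReason.ref_event
    if elapsed_cycles >= force_write_cycles:
        return TransmitReason.force_write
    return None


# ---------------------------------------------------------------------------
# Vectorized batch representation used by the simulator and preprocessing.
# ---------------------------------------------------------------------------


@dataclass
class FrameArray:
    """Column-oriented batch of frames.

    ``hit_frame`` indexes into the frame columns; hits are stored flat and
    sorted by (frame, channel).
    """

    step: np.ndarray  # uint16
    stop_code: np.ndarray  # uint8
    sync_valid: np.ndarray  # bool
    ref_pixel: np.ndarray  # bool
    ref_line: np.ndarray  # bool
    ref_frame: np.ndarray  # bool
    spare: np.ndarray  # uint8
    hit_frame: np.ndarray  # int64 index into frames
    hit_channel: np.ndarray  # uint8
    hit_code: np.ndarray  # uint8
    hit_valid: np.ndarray  # bool

    def __len__(self) -> int:
        return len(self.step)

    def __getitem__(self, k: int) -> FrameStructure:
        sel = self.hit_frame == k
        hits = {
            int(c): (int(v), bool(f))
            for c, v, f in zip(
                self.hit_channel[sel], self.hit_code[sel], self.hit_valid[sel]
            )
        }
        return FrameStructure(
            step=int(self.step[k]),
            stop_code=int(self.stop_code[k]),
            sync_valid=bool(self.sync_valid[k]),
            ref_pixel=bool(self.ref_pixel[k]),
            ref_line=bool(self.ref_line[k]),
            ref_frame=bool(self.ref_frame[k]),
            spare=int(self.spare[k]),
            hits=hits,
        )


def encode_frames(frames: FrameArray, n_channels: int = N_CHANNELS_DEFAULT) -> np.ndarray:
    """Vectorized encoder: FrameArray -> uint16 word array."""
    nf = len(frames)
    step = frames.step.astype(np.uint32)
    if frames.hit_channel.size and frames.hit_channel.max() >= n_channels:
        raise EncodingError("channel index not below n_channels")
    flags = (
        frames.ref_pixel.astype(np.uint32)
        | (frames.ref_line.astype(np.uint32) << 1)
        | (frames.ref_frame.astype(np.uint32) << 2)
        | (frames.sync_valid.astype(np.uint32) << 3)
    )
    header = np.empty((nf, N_HEADER_WORDS), dtype=np.uint32)
    header[:, 0] = (_ID_REF << 9) | (1 << 8) | flags
    header[:, 1] = (
        (_ID_STOP << 9)
        | (frames.sync_valid.astype(np.uint32) << 8)
        | frames.stop_code.astype(np.uint32)
    )
    header[:, 2] = (_ID_STEP_LO << 9) | (1 << 8) | (step & 0xFF)
    header[:, 3] = (_ID_STEP_HI << 9) | (1 << 8) | (step >> 8)
    header[:, 4] = (_ID_SPARE << 9) | (1 << 8) | frames.spare.astype(np.uint32)

    hit_words = (
        (frames.hit_channel.astype(np.uint32) << 9)
        | (frames.hit_valid.astype(np.uint32) << 8)
        | frames.hit_code.astype(np.uint32)
    )
    # interleave: header block of each frame followed by its hits
    n_hits_per = np.bincount(frames.hit_frame, minlength=nf)
    words_per = N_HEADER_WORDS + n_hits_per
    offsets = np.concatenate(([0], np.cumsum(words_per)))
    out = np.empty(offsets[-1], dtype=np.uint16)
    head_idx = offsets[:-1, None] + np.arange(N_HEADER_WORDS)
    out[head_idx.ravel()] = header.ravel().astype(np.uint16)
    if hit_words.size:
        # position of each hit word inside its frame block
        order = np.argsort(frames.hit_frame, kind="stable")
        hf = frames.hit_frame[order]
        within = np.arange(hf.size) - np.concatenate(([0], np.cumsum(n_hits_per)))[hf]
        out[offsets[hf] + N_HEADER_WORDS + within] = hit_words[order].astype(np.uint16)
    return out


def decode_words(
    raw: np.ndarray,
    n_channels: int = N_CHANNELS_DEFAULT,
    stats: DecodeStats | None = None,
) -> FrameArray:
    """Vectorized decoder: uint16 word array -> FrameArray.

    Integrity check mirrors :func:`decode_stream`: the five header ids must
    appear in order; frames failing the check are skipped and counted.
    """
    if stats is None:
        stats = DecodeStats()
    raw = np.asarray(raw, dtype=np.uint16)
    ids = (raw >> 9) & 0x7F
    valid = ((raw >> 8) & 1).astype(bool)
    payload = (raw & 0xFF).astype(np.uint16)

    starts = np.flatnonzero(ids == _ID_REF)
    good = np.ones(starts.size, dtype=bool)
    n = raw.size
    for off, want in enumerate(HEADER_IDS[1:], start=1):
        pos = starts + off
        ok = (pos < n) & (ids[np.minimum(pos, n - 1)] == want)
        good &= ok
    if starts.size and not good[-1] and starts[-1] + N_HEADER_WORDS > n:
        warnings.warn("truncated final frame dropped", stacklevel=2)
    fstart = starts[good]
    stats.corrupt_frames += int((~good).sum())
    stats.frames += int(fstart.size)

    flags = payload[fstart]
    frames_step = payload[fstart + 2] | (payload[fstart + 3] << 8)
    # channel words: any word with id < n_channels that follows a good header
    is_hit = ids < n_channels
    # words belonging to corrupted regions are discarded: a hit word counts
    # only if the nearest preceding header start is a good one
    if fstart.size:
        pos = np.arange(n)
        prev_good = np.searchsorted(fstart, pos, side="right") - 1
        owner_start = np.where(prev_good >= 0, fstart[np.maximum(prev_good, 0)], -1)
        hit_pos = np.flatnonzero(is_hit & (owner_start >= 0))
        # hits must come after their owner's header block
        hit_pos = hit_pos[hit_pos >= owner_start[hit_pos] + N_HEADER_WORDS]
        # and not be separated from the owner by a corrupt header start
        if (~good).any():
            bad_starts = starts[~good]
            prev_bad = np.searchsorted(bad_starts, hit_pos, side="right") - 1
            bad_before = np.where(prev_bad >= 0, bad_starts[np.maximum(prev_bad, 0)], -1)
            hit_pos = hit_pos[bad_before < owner_start[hit_pos]]
        owner = np.searchsorted(fstart, hit_pos, side="right") - 1
    else:
        hit_pos = np.empty(0, dtype=np.int64)
        owner = np.empty(0, dtype=np.int64)
    stats.discarded_words += int(n - fstart.size * N_HEADER_WORDS - hit_pos.size)

    return FrameArray(
        step=frames_step.astype(np.uint16),
        stop_code=payload[fstart + 1].astype(np.uint8),
        sync_valid=(flags & 0x8).astype(bool),
        ref_pixel=(flags & 0x1).astype(bool),
        ref_line=(flags & 0x2).astype(bool),
        ref_frame=(flags & 0x4).astype(bool),
        spare=payload[fstart + 4].astype(np.uint8),
        hit_frame=owner.astype(np.int64),
        hit_channel=ids[hit_pos].astype(np.uint8),
        hit_code=payload[hit_pos].astype(np.uint8),
        hit_valid=valid[hit_pos],
    )


def frames_to_array(frames: Iterable[FrameStructure]) -> FrameArray:
    """Build a FrameArray from FrameStructure objects."""
    frames = list(frames)
    hit_frame, hit_channel, hit_code, hit_valid = [], [], [], []
    for k, f in enumerate(frames):
        for ch in sorted(f.hits):
            code, v = f.hits[ch]
            hit_frame.append(k)
            hit_channel.append(ch)
            hit_code.append(code)
            hit_valid.append(v)
    return FrameArray(
        step=np.array([f.step for f in frames], dtype=np.uint16),
        stop_code=np.array([f.stop_code for f in frames], dtype=np.uint8),
        sync_valid=np.array([f.sync_valid for f in frames], dtype=bool),
        ref_pixel=np.array([f.ref_pixel for f in frames], dtype=bool),
        ref_line=np.array([f.ref_line for f in frames], dtype=bool),
        ref_frame=np.array([f.ref_frame for f in frames], dtype=bool),
        spare=np.array([f.spare for f in frames], dtype=np.uint8),
        hit_frame=np.array(hit_frame, dtype=np.int64),
        hit_channel=np.array(hit_channel, dtype=np.uint8),
        hit_code=np.array(hit_code, dtype=np.uint8),
        hit_valid=np.array(hit_valid, dtype=bool),
    )


def write_stream(path, words: np.ndarray) -> None:
    """Write a ``.ttm`` stream file (preamble + little-endian uint16 words)."""
    words = np.asarray(words, dtype="<u2")
    with open(path, "wb") as fh:
        fh.write(STREAM_MAGIC)
        fh.write(words.tobytes())


def read_stream(path) -> np.ndarray:
    """Read a ``.ttm`` stream file back into a uint16 word array."""
    with open(path, "rb") as fh:
        magic = fh.read(len(STREAM_MAGIC))
        if magic != STREAM_MAGIC:
            raise ValueError(f"not a ttm stream (bad preamble {magic!r})")
        return np.frombuffer(fh.read(), dtype="<u2").copy()


def pack_words(words: Iterable[DataWord]) -> np.ndarray:
    """Pack DataWord objects into a uint16 array."""
    return np.array([w.pack() for w in words], dtype=np.uint16)


def unpack_words(raw: np.ndarray) -> list:
    """Unpack a uint16 array into DataWord objects."""
    return [DataWord.unpack(int(r)) for r in np.asarray(raw)]
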