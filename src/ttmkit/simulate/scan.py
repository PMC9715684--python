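"""Raster-scan imaging simulator over a shifted-Gaussian detector array."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .decay import DecayModel


@dataclass
class DetectorGeometry:
    """Array of detection volumes displaced on a square grid.

    ``shift_vectors`` is the image-plane fingerprint (px): the image seen
    by element ``ch`` is the central-element image translated by
    ``shift_vectors[ch]``.  The central element has shift (0, 0).
    """

    n_elements: int = 25
    shift_vectors: np.ndarray = None  # (n_elements, 2) px, (sx, sy)
    psf_waist_um: float = 0.3  # 1/e^2 lateral radius of one element's PSF
    eccentricity: float = 4.5  # axial elongation k of the central volume
    pitch_um: float = 0.1  # sample-space projection of the element pitch

    def __post_init__(self) -> None:
        if self.shift_vectors is None:
            self.shift_vectors = self.grid_shifts(self.n_elements, 1.0)
        self.shift_vectors = np.asarray(self.shift_vectors, dtype=float)
        if self.shift_vectors.shape != (self.n_elements, 2):
            raise ValueError("shift_vectors must be (n_elements, 2)")
        centre = self.n_elements // 2
        if not np.allclose(self.shift_vectors[centre], 0):
            raise ValueError("central element must have zero shift")

    @staticmethod
    def grid_shifts(n_elements: int, pitch: float) -> np.ndarray:
        """Row-major square-grid offsets relative to the central element."""
        side = int(round(np.sqrt(n_elements)))
        if side * side != n_elements:
            raise ValueError("n_elements must be a perfect square")
        half = side // 2
        jj, ii = np.meshgrid(np.arange(side) - half, np.arange(side) - half)
        return np.stack([jj.ravel(), ii.ravel()], axis=1) * pitch

    @classmethod
    def grid(cls, n_side: int = 5, pitch_px: float = 0.8, **kw) -> "DetectorGeometry":
        n = n_side * n_side
        return cls(n_elements=n, shift_vectors=cls.grid_shifts(n, pitch_px), **kw)

    def sample_offsets_um(self) -> np.ndarray:
        """Sample-space lateral offsets of the detection volumes (um)."""
        return self.grid_shifts(self.n_elements, self.pitch_um)


@dataclass
class ScanConfig:
    """Scan trajectory description."""

    mode: str = "raster"  # raster | circular | point
    pixel_dwell_us: float = 20.0
    nx: int = 64
    ny: int = 64
    n_frames: int = 1
    radius_um: float = 0.0  # circular mode
    scan_period_us: float = 1000.0  # circular mode

    def __post_init__(self) -> None:
        if self.mode not in ("raster", "circular", "point"):
            raise ValueError(f"unknown scan mode {self.mode!r}")

    @property
    def frame_duration_ns(self) -> float:
        return self.nx * self.ny * self.pixel_dwell_us * 1e3

    @property
    def duration_ns(self) -> float:
        return self.n_frames * self.frame_duration_ns


@dataclass
class Emitter:
    x_px: float
    y_px: float
    brightness: float  # expected photons per dwell at beam == emitter (central ch)
    lifetime_ns: float = 4.0


def raster_ref_times(scan: ScanConfig):
    """Pixel/line/frame clock times (ns) for a raster scan.

    Frame, line and pixel events coincide at the start of each frame/line.
    """
    dwell = scan.pixel_dwell_us * 1e3
    n_px = scan.nx * scan.ny * scan.n_frames
    pixel = np.arange(n_px, dtype=float) * dwell
    line = np.arange(scan.ny * scan.n_frames, dtype=float) * (scan.nx * dwell)
    frame = np.arange(scan.n_frames, dtype=float) * scan.frame_duration_ns
    return pixel, line, frame


def expected_channel_images(
    emitters, geometry: DetectorGeometry, scan: ScanConfig, psf_sigma_px: float
) -> np.ndarray:
    """Noise-free expected counts per (ch, x, y) for one raster frame."""
    xs = np.arange(scan.nx, dtype=float)
    ys = np.arange(scan.ny, dtype=float)
    bx, by = np.meshgrid(xs, ys, indexing="ij")
    out = np.zeros((geometry.n_elements, scan.nx, scan.ny))
    for ch in range(geometry.n_elements):
        sx, sy = geometry.shift_vectors[ch]
        for e in emitters:
            # image of channel ch = central image translated by (sx, sy)
            out[ch] += e.brightness * np.exp(
                -(((bx - e.x_px - sx) ** 2) + ((by - e.y_px - sy) ** 2))
                / (2 * psf_sigma_px**2)
            )
    return out


def simulate_scan(
    emitters,
    geometry: DetectorGeometry,
    scan: ScanConfig,
    decay: DecayModel,
    seed: int,
    psf_sigma_px: float = 1.5,
    sync_phase_ns: float = 0.0,
):
    """Simulate a raster scan; returns a dict of photon/ref ground truth.

    Photon absolute times are laid on the laser SYNC grid: each photon is
    placed at (sync time - 0) + its start--stop delay relative to the
    preceding pulse, uniformly distributed over its pixel dwell window.
    """
    if scan.mode != "raster":
        raise ValueError("simulate_scan handles raster mode")
    rng = np.random.default_rng(seed)
    dwell = scan.pixel_dwell_us * 1e3
    period = decay.laser_period_ns
    lam = expected_channel_images(emitters, geometry, scan, psf_sigma_px)

    counts = rng.poisson(np.broadcast_to(lam[..., None], lam.shape + (scan.n_frames,)))
    ch_idx, x_idx, y_idx, fr_idx = np.nonzero(counts)
    reps = counts[ch_idx, x_idx, y_idx, fr_idx]
    ch = np.repeat(ch_idx, reps)
    x = np.repeat(x_idx, reps)
    y = np.repeat(y_idx, reps)
    fr = np.repeat(fr_idx, reps)
    n_ph = ch.size

    # pixel start time: raster order is x fastest within a line
    pix_start = (
        fr * scan.frame_duration_ns + y * (scan.nx * dwell) + x * dwell
    ).astype(float)
    dt = decay.sample_start_stop(n_ph, rng)
    # choose the laser pulse preceding each photon, uniform over the dwell;
    # keep one laser period of guard band so no photon straddles a pixel
    # boundary's coarse window
    n_pulses_dwell = max(int(dwell / period) - 2, 1)
    pulse = np.floor(rng.random(n_ph) * n_pulses_dwell)
    t_sync_prev = sync_phase_ns + (
        np.floor((pix_start - sync_phase_ns) / period) + 1 + pulse
    ) * period
    t_abs = t_sync_prev + dt

    order = np.argsort(t_abs, kind="stable")
    pixel, line, frame = raster_ref_times(scan)
    return {
        "t_abs_ns": t_abs[order],
        "dt_ns": dt[order],
        "channel": ch[order],
        "x": x[order],
        "y": y[order],
        "frame": fr[order],
        "ref_pixel_ns": pixel,
        "ref_line_ns": line,
        "ref_frame_ns": frame,
        "laser_period_ns": period,
        "sync_phase_ns": sync_phase_ns,
        "duration_ns": scan.duration_ns,
        "expected_images": lam,
    }
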