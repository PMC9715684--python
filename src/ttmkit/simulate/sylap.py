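"""Fixed-frequency test-signal generator (SYLAP-style).

Produces a clock train used as the laser SYNC surrogate and a decimated,
delayed and optionally jittered pulse train used as the photon surrogate.
Delay is quantized to a 39.0625 ps grid and the clock period to a 2.5 ns
grid, mirroring the generator hardware granularity.
"""

from __future__ import annotations

import warnings

import numpy as np

DELAY_GRID_NS = 0.0390625
PERIOD_GRID_NS = 2.5


def _snap(value: float, grid: float, name: str) -> float:
    snapped = round(value / grid) * grid
    if abs(snapped - value) > 1e-12:
        warnings.warn(
            f"{name}={value} ns not on the {grid} ns grid; rounded to {snapped} ns",
            stacklevel=3,
        )
    return snapped


def simulate_sylap(
    clock_period_ns: float = 20.0,
    pulse_delay_ns: float = 5.0,
    decimation: int = 30,
    jitter_sigma_ns: float = 0.0,
    n_events: int = 100_000,
    seed: int = 0,
    phase_ns: float = 0.0,
):
    """Return ``(sync_times_ns, photon_times_ns)``.

    Photons sit on every ``decimation``-th sync plus the (grid-snapped)
    delay plus Gaussian jitter.  ``phase_ns`` offsets the whole train
    against the acquisition clock.
    """
    if decimation < 1:
        raise ValueError("decimation must be >= 1")
    period = _snap(clock_period_ns, PERIOD_GRID_NS, "clock_period_ns")
    delay = _snap(pulse_delay_ns, DELAY_GRID_NS, "pulse_delay_ns")
    rng = np.random.default_rng(seed)
    n_sync = n_events * decimation + 1
    sync = phase_ns + period * np.arange(n_sync, dtype=float)
    photons = sync[::decimation][:n_events] + delay
    if jitter_sigma_ns > 0:
        photons = photons + rng.normal(0.0, jitter_sigma_ns, photons.size)
    return sync, photons
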