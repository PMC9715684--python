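"""Fluorescence decay photon generator.

Start--stop times follow Exp(tau) convolved with a Gaussian IRF, folded
modulo the laser period, mixed with a uniform background fraction.
Optional detector artefacts: cross-talk (a coincident echo on a
neighbouring channel with a small extra delay bump) and afterpulsing (an
exponential-tail echo on the same channel).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np


@dataclass
class DecayModel:
    """Single-exponential emission model plus instrument terms."""

    lifetime_ns: float = 4.0
    irf_sigma_ns: float = 0.0
    background_fraction: float = 0.0
    laser_period_ns: float = 25.0
    crosstalk_prob: float = 0.0
    afterpulse_prob: float = 0.0
    afterpulse_tau_ns: float = 5.0
    crosstalk_delay_ns: float = 0.3
    crosstalk_sigma_ns: float = 0.1

    def __post_init__(self) -> None:
        if not 0 <= self.background_fraction < 1:
            raise ValueError("background_fraction must be in [0, 1)")
        if min(self.lifetime_ns, self.laser_period_ns) <= 0:
            raise ValueError("lifetime and laser period must be positive")

    def sample_start_stop(self, n: int, rng: np.random.Generator) -> np.ndarray:
        """Draw n start--stop times (ns) in [0, laser_period)."""
        is_bg = rng.random(n) < self.background_fraction
        dt = rng.exponential(self.lifetime_ns, n)
        if self.irf_sigma_ns > 0:
            dt += rng.normal(0.0, self.irf_sigma_ns, n)
        dt[is_bg] = rng.random(is_bg.sum()) * self.laser_period_ns
        return np.mod(dt, self.laser_period_ns)


def simulate_decay_photons(
    model: DecayModel,
    n_pulses: int,
    rate_per_pulse: float,
    seed: int,
    channel: int = 12,
    n_side: int = 5,
    t0_ns: float = 0.0,
):
    """Generate photons for a pulsed-laser run at a fixed detection channel.

    ``rate_per_pulse`` is the detection probability per laser pulse and
    should be << 1 (single-photon regime).  Returns
    ``(absolute_times_ns, start_stop_ns, channels)`` sorted by absolute
    time.  Absolute time is the emission time: the time of the *preceding*
    laser pulse plus the start--stop time.
    """
    rng = np.random.default_rng(seed)
    period = model.laser_period_ns
    hit = rng.random(n_pulses) < rate_per_pulse
    pulse_idx = np.flatnonzero(hit)
    dt = model.sample_start_stop(pulse_idx.size, rng)
    t_abs = t0_ns + pulse_idx * period + dt
    ch = np.full(pulse_idx.size, channel, dtype=np.int64)

    extras_t, extras_dt, extras_ch = [], [], []
    if model.crosstalk_prob > 0 and pulse_idx.size:
        echo = rng.random(dt.size) < model.crosstalk_prob
        idx = np.flatnonzero(echo)
        i, j = divmod(channel, n_side)
        moves = [(0, 1), (0, -1), (1, 0), (-1, 0)]
        pick = rng.integers(0, 4, idx.size)
        ni = np.clip(i + np.array([moves[p][0] for p in pick]), 0, n_side - 1)
        nj = np.clip(j + np.array([moves[p][1] for p in pick]), 0, n_side - 1)
        bump = model.crosstalk_delay_ns + rng.normal(0, model.crosstalk_sigma_ns, idx.size)
        extras_t.append(t_abs[idx] + np.abs(bump))
        extras_dt.append(np.mod(dt[idx] + np.abs(bump), period))
        extras_ch.append(ni * n_side + nj)
    if model.afterpulse_prob > 0 and pulse_idx.size:
        echo = rng.random(dt.size) < model.afterpulse_prob
        idx = np.flatnonzero(echo)
        tail = rng.exponential(model.afterpulse_tau_ns, idx.size)
        extras_t.append(t_abs[idx] + tail)
        extras_dt.append(np.mod(dt[idx] + tail, period))
        extras_ch.append(np.full(idx.size, channel, dtype=np.int64))

    if extras_t:
        t_abs = np.concatenate([t_abs] + extras_t)
        dt = np.concatenate([dt] + extras_dt)
        ch = np.concatenate([ch] + extras_ch)
    order = np.argsort(t_abs, kind="stable")
    return t_abs[order], dt[order], ch[order]
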