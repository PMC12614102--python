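"""Render per-antenna intermediate-band complex signals.

Each antenna sees the FM-encoded transmitter tone through its complex channel
gain plus independent circularly symmetric Gaussian receiver noise:

    z_a(t) = amp_a(t) * exp(i * [phi(t) + phase_a(t)]) + n_a(t)

where ``phi`` accumulates ``2*pi*(omega_T - omega_LO)/F_z`` per sample, in
double precision with wrapping.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from numba import njit

from fmtelem.radio_sim.channel import ANTENNAS, ChannelRealization

__all__ = ["IntermediateSignalSet", "render_antennas", "accumulate_wrapped_phase"]


@njit(cache=True)
def _accum_phase(freq_rel_hz, rate_hz, out):  # pragma: no cover - numba
    two_pi = 2.0 * np.pi
    phi = 0.0
    for n in range(freq_rel_hz.shape[0]):
        phi += two_pi * freq_rel_hz[n] / rate_hz
        while phi > np.pi:
            phi -= two_pi
        while phi <= -np.pi:
            phi += two_pi
        out[n] = phi


def accumulate_wrapped_phase(freq_rel_hz: np.ndarray, rate_hz: float) -> np.ndarray:
    """Integrate an instantaneous frequency into a wrapped phase (radians)."""
    freq_rel_hz = np.ascontiguousarray(freq_rel_hz, dtype=np.float64)
    out = np.empty_like(freq_rel_hz)
    _accum_phase(freq_rel_hz, float(rate_hz), out)
    return out


@dataclass
class IntermediateSignalSet:
    """Four equal-length complex antenna sequences at the intermediate rate."""

    z: np.ndarray  # (4, n) complex128
    rate_hz: float
    lo_hz: float
    antennas: tuple[str, ...] = ANTENNAS

    def __post_init__(self) -> None:
        self.z = np.atleast_2d(np.asarray(self.z, dtype=np.complex128))
        if self.z.shape[0] != len(self.antennas):
            raise ValueError("one sequence per antenna is required")
        if not np.all(np.isfinite(self.z)):
            raise ValueError("intermediate signals must be finite")

    @property
    def duration_s(self) -> float:
        return self.z.shape[1] / self.rate_hz

    @property
    def band_hz(self) -> tuple[float, float]:
        return (self.lo_hz - self.rate_hz / 2, self.lo_hz + self.rate_hz / 2)


def render_antennas(
    omega_t: np.ndarray,
    channel: ChannelRealization,
    lo_hz: float,
    rate_hz: float,
    seed: int,
) -> IntermediateSignalSet:
    """Render an instantaneous-frequency trajectory through a channel.

    Parameters
    ----------
    omega_t:
        Transmitter frequency trajectory in absolute Hz, sampled at
        ``rate_hz``.
    channel:
        Complex gain trajectories and per-antenna noise sigma.
    lo_hz, rate_hz:
        Local oscillator and complex sample rate of the intermediate band.
    seed:
        Noise seed; identical seeds give bit-identical output.

    Raises
    ------
    ValueError
        If ``|omega_t - lo_hz|`` reaches ``rate_hz/2`` anywhere (aliasing).
    """
    omega_t = np.asarray(omega_t, dtype=np.float64)
    f_rel = omega_t - lo_hz
    bad = np.flatnonzero(np.abs(f_rel) >= rate_hz / 2)
    if bad.size:
        raise ValueError(
            f"transmitter frequency aliases at t = {bad[0] / rate_hz:.6f} s: "
            f"|omega_T - omega_LO| = {abs(f_rel[bad[0]]):.0f} Hz >= rate/2"
        )
    phi = accumulate_wrapped_phase(f_rel, rate_hz)
    t = np.arange(omega_t.size) / rate_hz
    amp, ph = channel.sample(t)

    rng = np.random.default_rng(seed)
    z = np.empty((len(ANTENNAS), omega_t.size), dtype=np.complex128)
    for a in range(len(ANTENNAS)):
        z[a] = amp[a] * np.exp(1j * (phi + ph[a]))
        sigma = channel.noise_sigma[a]
        if sigma > 0:
            scale = sigma / np.sqrt(2.0)
            z[a] += scale * rng.standard_normal(omega_t.size)
            z[a] += 1j * scale * rng.standard_normal(omega_t.size)
    return IntermediateSignalSet(z, rate_hz, lo_hz)
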