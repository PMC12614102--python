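"""Per-antenna complex channel gains: amplitude/phase trajectories and fades.

Fading is modeled as prescribed, slowly varying amplitude and phase
trajectories per antenna rather than ray-traced multipath; the downstream
algorithms only ever see the complex gains.  Trajectories are stored at
breakpoints and linearly interpolated at render time.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

__all__ = ["ANTENNAS", "FadeInterval", "ChannelRealization", "make_fading_scenario"]

ANTENNAS = ("A", "B", "C", "D")


@dataclass(frozen=True)
class FadeInterval:
    """Ground-truth fade of one antenna: support of the amplitude dip."""

    antenna: str
    onset_s: float
    offset_s: float


@dataclass
class ChannelRealization:
    """Amplitude/phase gain trajectories and noise levels for four antennas.

    ``times_s`` holds shared breakpoints; ``amplitudes`` and ``phases`` are
    ``(4, len(times_s))`` arrays, linearly interpolated at render time.
    ``noise_sigma`` is the per-antenna standard deviation of the additive
    circularly symmetric complex receiver noise (``E|n|^2 = sigma^2``).
    """

    times_s: np.ndarray
    amplitudes: np.ndarray
    phases: np.ndarray
    noise_sigma: np.ndarray
    seed: int = 0
    fade_intervals: list[FadeInterval] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.times_s = np.asarray(self.times_s, dtype=np.float64)
        self.amplitudes = np.atleast_2d(np.asarray(self.amplitudes, dtype=np.float64))
        self.phases = np.atleast_2d(np.asarray(self.phases, dtype=np.float64))
        self.noise_sigma = np.broadcast_to(
            np.asarray(self.noise_sigma, dtype=np.float64), (len(ANTENNAS),)
        ).copy()
        if self.amplitudes.shape != (len(ANTENNAS), self.times_s.size):
            raise ValueError("amplitudes must have shape (4, n_breakpoints)")
        if self.phases.shape != self.amplitudes.shape:
            raise ValueError("phases must match the amplitude trajectory shape")
        if np.any(self.amplitudes < 0):
            raise ValueError("gain amplitudes must be non-negative")
        if np.any(self.noise_sigma < 0):
            raise ValueError("noise sigma must be non-negative")

    @classmethod
    def constant(
        cls,
        amplitudes: Sequence[float] = (1.0, 1.0, 1.0, 1.0),
        phases: Sequence[float] = (0.0, 0.0, 0.0, 0.0),
        noise_sigma: float | Sequence[float] = 0.0,
        duration_s: float = 1.0,
        seed: int = 0,
    ) -> "ChannelRealization":
        """Time-invariant channel, handy for unit tests."""
        times = np.array([0.0, duration_s])
        amp = np.repeat(np.asarray(amplitudes, dtype=float)[:, None], 2, axis=1)
        ph = np.repeat(np.asarray(phases, dtype=float)[:, None], 2, axis=1)
        return cls(times, amp, ph, np.broadcast_to(np.asarray(noise_sigma, float), (4,)), seed)

    def sample(self, t: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Interpolate (amplitudes, phases) at times ``t``; each ``(4, len(t))``."""
        amp = np.empty((len(ANTENNAS), t.size))
        ph = np.empty((len(ANTENNAS), t.size))
        for a in range(len(ANTENNAS)):
            amp[a] = np.interp(t, self.times_s, self.amplitudes[a])
            ph[a] = np.interp(t, self.times_s, self.phases[a])
        return amp, ph


def make_fading_scenario(
    duration_s: float,
    seed: int,
    noise_sigma: float = 0.02,
    base_amplitude: float = 1.0,
    fade_floor: float = 0.01,
    fade_width_s: float | None = None,
) -> ChannelRealization:
    """Adversarial fading: one deep, non-overlapping fade per antenna.

    The duration is split into four slots; each antenna receives a single
    raised-cosine amplitude dip (down to ``fade_floor`` < 0.02) confined to
    its slot, so at any instant the other three antennas sit at
    ``base_amplitude``.  Antenna order and dip centers are randomized by
    ``seed``; phases are random constants per antenna.
    """
    if duration_s <= 0:
        raise ValueError("duration must be positive")
    if not 0 <= fade_floor < 0.02:
        raise ValueError("fade floor must be a deep fade (< 0.02)")
    rng = np.random.default_rng(seed)
    n_ant = len(ANTENNAS)
    slot = duration_s / n_ant
    if fade_width_s is None:
        fade_width_s = 0.5 * slot
    width = min(fade_width_s, 0.7 * slot)

    grid = np.linspace(0.0, duration_s, max(int(duration_s * 200), 16) + 1)
    amplitudes = np.full((n_ant, grid.size), float(base_amplitude))
    phases = np.empty((n_ant, grid.size))

    order = rng.permutation(n_ant)
    centers = np.empty(n_ant)
    for k, a in enumerate(order):
        jitter = rng.uniform(-0.1, 0.1) * slot
        centers[a] = (k + 0.5) * slot + jitter
    fade_intervals = []
    for a in range(n_ant):
        x = (grid - centers[a]) / width
        dip = np.zeros_like(grid)
        m = np.abs(x) < 0.5
        dip[m] = 0.5 * (1.0 + np.cos(2.0 * np.pi * x[m]))
        amplitudes[a] -= (base_amplitude - fade_floor) * dip
        phases[a, :] = rng.uniform(-np.pi, np.pi)
        fade_intervals.append(
            FadeInterval(ANTENNAS[a], centers[a] - width / 2, centers[a] + width / 2)
        )
    fade_intervals.sort(key=lambda f: f.onset_s)
    return ChannelRealization(
        grid,
        amplitudes,
        phases,
        np.full(n_ant, float(noise_sigma)),
        seed=seed,
        fade_intervals=fade_intervals,
    )
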