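"""Demodulator configuration."""

from __future__ import annotations

from dataclasses import dataclass, replace

from fmtelem.presets import PRESETS

__all__ = ["DemodConfig"]


@dataclass(frozen=True)
class DemodConfig:
    """Per-channel tracking and compensation parameters.

    ``kp``/``ki``/``kd`` are the PID gains in physical units (Hz of tracking
    frequency per turn of phase error, per turn-second, and per turn/second).
    When left ``None`` they default to ``kp_norm * f_bb`` and
    ``ki_norm * f_bb**2`` where ``f_bb`` is the baseband rate; the normalized
    defaults are tuned per preset with :func:`measure_closed_loop` so that
    the closed-loop bandwidth scales with the baseband rate.
    """

    center_hz: float
    limit_hz: float = 1e6
    decimation: int = 128
    passband_hz: float = 1e5
    block: int = 512
    gamma: float = 0.2
    unwrap_turns: int = 128
    kp: float | None = None
    ki: float | None = None
    kd: float = 0.0
    log_decimation: int = 32
    kp_norm: float = 0.08
    ki_norm: float = 3e-4

    def __post_init__(self) -> None:
        if not 0.0 <= self.gamma <= 1.0:
            raise ValueError("gamma must lie in [0, 1]")
        if self.block < 1:
            raise ValueError("block length must be >= 1")
        if self.limit_hz <= 0:
            raise ValueError("limit must be positive")
        if self.log_decimation < 1:
            raise ValueError("log decimation must be >= 1")
        if self.unwrap_turns < 1:
            raise ValueError("unwrap range must be >= 1 turn")

    @classmethod
    def from_preset(cls, preset: str, center_hz: float, **overrides) -> "DemodConfig":
        p = PRESETS[preset]
        cfg = cls(
            center_hz=center_hz,
            limit_hz=p.limit_hz,
            decimation=p.decimation,
            passband_hz=p.passband_hz,
            block=p.block,
            log_decimation=p.log_decimation,
            kp_norm=p.kp_norm,
            ki_norm=p.ki_norm,
        )
        return replace(cfg, **overrides) if overrides else cfg

    def gains(self, baseband_rate_hz: float) -> tuple[float, float, float]:
        kp = self.kp if self.kp is not None else self.kp_norm * baseband_rate_hz
        ki = self.ki if self.ki is not None else self.ki_norm * baseband_rate_hz**2
        return kp, ki, self.kd
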