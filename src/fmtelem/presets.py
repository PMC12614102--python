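"""Rate presets for the simulator and demodulator.

The ``fullrate`` preset records the acquisition arithmetic of the original
hardware (100 MS/s intermediate band, local oscillator at 300 MHz,
decimation by 128 to a 781.25 kHz baseband, frequency log at 1/32 of the
baseband rate).  It is used for rate bookkeeping and documentation; running
full-rate simulations on a desktop is not practical.

The ``desk`` preset scales the intermediate band down to 1 MS/s while keeping
every physical threshold (Hz, Hz/s, g) in real units.  The tracking-loop
algorithms are rate invariant, so the desk preset exercises the identical
code path at a tractable sample rate.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

__all__ = ["Preset", "PRESETS"]


@dataclass(frozen=True)
class Preset:
    """Bundle of rate and loop parameters for one operating point.

    Attributes
    ----------
    rate_hz:
        Complex sample rate of the intermediate band (F_z).
    lo_hz:
        Local oscillator frequency; the intermediate band covers
        ``lo_hz +- rate_hz/2``.
    decimation:
        Down-converter decimation factor D; baseband rate is ``rate_hz/D``.
    passband_hz:
        Half width of the flat band of the decimation filter.
    limit_hz:
        Tracking limit; the tracking frequency is confined to the channel
        center +- ``limit_hz``.
    block:
        Phase-compensation block length in baseband samples.
    log_decimation:
        Output decimation of the logged tracking frequency.
    frame_len:
        Logged samples per ~21 ms radio frame at this preset's log rate.
    kp_norm, ki_norm:
        Default PID gains normalized by the baseband rate: the physical
        gains are ``kp_norm * f_bb`` (Hz per turn of phase error) and
        ``ki_norm * f_bb**2`` (Hz per turn-second).
    """

    name: str
    rate_hz: float
    lo_hz: float
    decimation: int
    passband_hz: float
    limit_hz: float
    block: int
    log_decimation: int
    frame_len: int
    kp_norm: float
    ki_norm: float

    @property
    def baseband_rate_hz(self) -> float:
        return self.rate_hz / self.decimation

    @property
    def log_rate_hz(self) -> float:
        return self.baseband_rate_hz / self.log_decimation

    @property
    def frame_s(self) -> float:
        return self.frame_len / self.log_rate_hz


PRESETS: dict[str, Preset] = {
    "desk": Preset(
        name="desk",
        rate_hz=1e6,
        lo_hz=300e6,
        decimation=2,
        passband_hz=6e3,
        limit_hz=1e5,
        block=512,
        log_decimation=16,
        frame_len=656,  # 20.99 ms at 31.25 kHz log rate
        kp_norm=0.05,  # ~4 kHz closed-loop bandwidth at 500 kHz baseband
        ki_norm=5e-5,
    ),
    "fullrate": Preset(
        name="fullrate",
        rate_hz=100e6,
        lo_hz=300e6,
        decimation=128,
        passband_hz=1e5,
        limit_hz=1e6,
        block=512,
        log_decimation=32,
        frame_len=512,  # 20.97 ms at 24.414 kHz log rate
        kp_norm=2 * math.pi * 30e3 / 781.25e3,  # ~30 kHz closed-loop bandwidth
        ki_norm=3e-4,
    ),
}
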