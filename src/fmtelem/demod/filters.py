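"""Decimation-filter design for the digital down-converters.

Contract: passband ripple <= 0.1 dB over +-``passband_hz``, and >= 60 dB
attenuation beyond the stopband edge, by default the decimated Nyquist
frequency ``F_z/(2D)``.  A sharper stopband edge can be requested for
open-loop use; inside the tracking loop the wide default transition keeps
the filter short, since its group delay adds directly to the loop delay of
the PLL.  For large decimation factors the filter is split into a mild
anti-alias stage (decimate by D/4) followed by the sharp stage (decimate by
4) at the reduced rate.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal

__all__ = ["DecimatorDesign", "design_decimator"]

_ATTEN_DB = 65.0  # design margin over the 60 dB requirement


@dataclass(frozen=True)
class DecimatorDesign:
    h1: np.ndarray  # stage-1 taps at rate_hz (trivial [1.0] when single stage)
    h2: np.ndarray  # stage-2 taps at rate_hz/d1
    d1: int
    d2: int
    rate_hz: float
    passband_hz: float
    stopband_hz: float

    @property
    def decimation(self) -> int:
        return self.d1 * self.d2

    @property
    def baseband_rate_hz(self) -> float:
        return self.rate_hz / self.decimation


def _kaiser_lowpass(rate_hz: float, pass_hz: float, stop_hz: float) -> np.ndarray:
    numtaps, beta = signal.kaiserord(_ATTEN_DB, (stop_hz - pass_hz) / (rate_hz / 2))
    numtaps |= 1  # odd length, linear phase type I
    h = signal.firwin(
        numtaps, (pass_hz + stop_hz) / 2, window=("kaiser", beta), fs=rate_hz
    )
    return h / h.sum()  # exact unit DC gain


def design_decimator(
    rate_hz: float,
    decimation: int,
    passband_hz: float,
    stopband_hz: float | None = None,
) -> DecimatorDesign:
    if decimation < 1:
        raise ValueError("decimation must be >= 1")
    f_bb = rate_hz / decimation
    if passband_hz >= f_bb / 2:
        raise ValueError("passband must be below the decimated Nyquist frequency")
    f_stop = f_bb / 2 if stopband_hz is None else float(stopband_hz)
    if not passband_hz < f_stop <= f_bb / 2:
        raise ValueError("stopband edge must lie in (passband, decimated Nyquist]")
    if decimation >= 16 and decimation % 4 == 0:
        d1, d2 = decimation // 4, 4
        f_mid = rate_hz / d1
        h1 = _kaiser_lowpass(rate_hz, f_stop, f_mid - f_stop)
        h2 = _kaiser_lowpass(f_mid, passband_hz, f_stop)
    else:
        d1, d2 = 1, decimation
        h1 = np.array([1.0])
        h2 = _kaiser_lowpass(rate_hz, passband_hz, f_stop)
    return DecimatorDesign(h1, h2, d1, d2, rate_hz, passband_hz, f_stop)
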