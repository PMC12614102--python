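"""Spectrogram used for visual QC and to define the overlap quantum."""

from __future__ import annotations

import numpy as np
from scipy import signal as sp_signal

__all__ = ["spectrogram", "bin_duration_s"]


def bin_duration_s(rate_hz: float, hop: int = 96) -> float:
    """Duration of one spectrogram time bin: ``hop / rate``."""
    return hop / rate_hz


def spectrogram(
    x: np.ndarray,
    rate_hz: float,
    window: int = 384,
    hop: int = 96,
) -> tuple[np.ndarray, np.ndarray, np.ndarray, float]:
    """Magnitude spectrogram with ``floor((N - window)/hop) + 1`` frames.

    Returns ``(freqs_hz, times_s, magnitude, bin_s)`` where magnitude has
    shape ``(n_freqs, n_frames)``.
    """
    x = np.asarray(x, dtype=np.float64)
    if x.size < window:
        raise ValueError("signal shorter than one analysis window")
    f, t, s = sp_signal.spectrogram(
        x,
        fs=rate_hz,
        window="hann",
        nperseg=window,
        noverlap=window - hop,
        mode="magnitude",
        detrend=False,
    )
    return f, t, s, bin_duration_s(rate_hz, hop)
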