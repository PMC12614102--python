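"""Radio signal-to-noise statistics of compensated baseband signals.

Per non-overlapping ~21 ms radio frame k the signal power is the squared
magnitude of the frame mean, ``p(t_k) = |<r>|^2``, and the frame noise
variance is ``<|r|^2> - |<r>|^2``.  For smoothness the per-file noise
variance ``v`` is the median of the frame variances, and

    RSNR(t_k) = 10*log10(p(t_k) / v).

Sources are the four antennas A-D and the phase-compensated sum M.  Both
statistics are invariant to any constant phase rotation of the input, so
they are computed from the compensated (unrotated) baseband vectors; under
lock these coincide with the rotated vectors of the compensation loop.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import numpy as np
from scipy import signal as sp_signal

from fmtelem.demod.loop import DemodOutput

__all__ = [
    "RSNRFrameSeries",
    "NoiseEstimate",
    "rsnr_frames",
    "rsnr_frames_from_blocks",
    "best_single_antenna",
    "fading_stats",
    "noise_power",
]


@dataclass
class RSNRFrameSeries:
    """Per-frame power/variance/RSNR for sources A-D and M.

    Frames where the noise variance is exactly zero carry an RSNR of +inf;
    such frames are excluded from summary statistics.
    """

    t: np.ndarray
    frame_len: int
    rate_hz: float
    power: dict[str, np.ndarray]
    noise: dict[str, float]
    rsnr_db: dict[str, np.ndarray]

    @property
    def sources(self) -> tuple[str, ...]:
        return tuple(self.rsnr_db)

    @property
    def n_frames(self) -> int:
        return self.t.size

    @property
    def frame_s(self) -> float:
        return self.frame_len / self.rate_hz


def _frame_stats(r: np.ndarray, frame_len: int) -> tuple[np.ndarray, np.ndarray]:
    n_frames = r.size // frame_len
    frames = r[: n_frames * frame_len].reshape(n_frames, frame_len)
    mean = frames.mean(axis=1)
    p = np.abs(mean) ** 2
    v = (np.abs(frames) ** 2).mean(axis=1) - p
    return p, np.maximum(v, 0.0)


def rsnr_frames(
    sources: Mapping[str, np.ndarray] | DemodOutput,
    frame_len: int,
    rate_hz: float | None = None,
) -> RSNRFrameSeries:
    """Frame-wise RSNR from raw compensated baseband sequences.

    Accepts either a mapping source -> complex sequence (all equal length)
    or a :class:`DemodOutput`, in which case the per-antenna sequences are
    taken from the log and M is their sum.  A trailing partial frame is
    dropped so frames are non-overlapping and contiguous.
    """
    if isinstance(sources, DemodOutput):
        rate_hz = sources.log_rate_hz
        sources = sources.baseband_sources()
    if rate_hz is None:
        raise ValueError("rate_hz is required when passing raw sequences")
    lengths = {np.asarray(x).size for x in sources.values()}
    if len(lengths) != 1:
        raise ValueError("all sources must cover an identical time span")
    if frame_len < 2:
        raise ValueError("frame length must be >= 2 samples")
    power: dict[str, np.ndarray] = {}
    noise: dict[str, float] = {}
    rsnr_db: dict[str, np.ndarray] = {}
    n_frames = lengths.pop() // frame_len
    for name, r in sources.items():
        p, v = _frame_stats(np.asarray(r), frame_len)
        v_file = float(np.median(v))
        power[name] = p
        noise[name] = v_file
        with np.errstate(divide="ignore"):
            rsnr_db[name] = np.where(
                v_file > 0, 10.0 * np.log10(np.maximum(p, 1e-300) / max(v_file, 1e-300)), np.inf
            )
    t = (np.arange(n_frames) + 0.5) * frame_len / rate_hz
    return RSNRFrameSeries(t, frame_len, rate_hz, power, noise, rsnr_db)


def rsnr_frames_from_blocks(
    r_block_mean: np.ndarray,
    r_block_power: np.ndarray,
    block_rate_hz: float,
    blocks_per_frame: int,
    sources: tuple[str, ...] = ("A", "B", "C", "D", "M"),
) -> RSNRFrameSeries:
    """Frame-wise RSNR from logged per-block first/second moments.

    A frame aggregates ``blocks_per_frame`` consecutive blocks; its mean is
    the mean of block means and its second moment the mean of block powers.
    """
    n_src, n_blk = r_block_mean.shape
    n_frames = n_blk // blocks_per_frame
    power: dict[str, np.ndarray] = {}
    noise: dict[str, float] = {}
    rsnr_db: dict[str, np.ndarray] = {}
    for i, name in enumerate(sources[:n_src]):
        m = r_block_mean[i, : n_frames * blocks_per_frame].reshape(n_frames, blocks_per_frame)
        q = r_block_power[i, : n_frames * blocks_per_frame].reshape(n_frames, blocks_per_frame)
        mean = m.mean(axis=1)
        p = np.abs(mean) ** 2
        v = np.maximum(q.mean(axis=1) - p, 0.0)
        v_file = float(np.median(v))
        power[name] = p
        noise[name] = v_file
        with np.errstate(divide="ignore"):
            rsnr_db[name] = np.where(
                v_file > 0, 10.0 * np.log10(np.maximum(p, 1e-300) / max(v_file, 1e-300)), np.inf
            )
    frame_len = blocks_per_frame
    t = (np.arange(n_frames) + 0.5) * blocks_per_frame / block_rate_hz
    return RSNRFrameSeries(t, frame_len, block_rate_hz, power, noise, rsnr_db)


def best_single_antenna(series: RSNRFrameSeries) -> tuple[str, np.ndarray]:
    """Select the antenna with the largest time-averaged RSNR.

    Returns the chosen label and its per-frame RSNR trace.  Ties break to
    the lowest antenna label.  Frames with infinite RSNR are excluded from
    the average.
    """
    best_label = None
    best_mean = -np.inf
    for label in sorted(k for k in series.rsnr_db if k != "M"):
        trace = series.rsnr_db[label]
        finite = trace[np.isfinite(trace)]
        mean = finite.mean() if finite.size else -np.inf
        if mean > best_mean:
            best_mean = mean
            best_label = label
    if best_label is None:
        raise ValueError("no antenna sources present")
    return best_label, series.rsnr_db[best_label]


def fading_stats(series: RSNRFrameSeries, threshold_db: float = 13.0) -> dict[str, float]:
    """Percent of time each source spends below the critical RSNR."""
    out = {}
    for name, trace in series.rsnr_db.items():
        out[name] = 100.0 * float(np.mean(trace < threshold_db))
    return out


@dataclass(frozen=True)
class NoiseEstimate:
    """Integrated 0..f_max PSD of the demodulated signal on non-vocal data."""

    p_n_db: float
    p_n_linear: float
    f_max_hz: float


def noise_power(
    demod_signal: np.ndarray,
    rate_hz: float,
    non_vocal_segments: list[tuple[float, float]],
    f_max_hz: float = 8e3,
    nperseg: int = 1024,
) -> NoiseEstimate:
    """Noise power P_N of the demodulated signal during non-vocal periods.

    Welch PSDs (Hann window, 50% overlap) of every usable non-vocal segment
    are averaged weighted by segment length and integrated from 0 to
    ``f_max_hz``; the result is reported in dB (re 1 Hz^2 for a signal in
    Hz).
    """
    demod_signal = np.asarray(demod_signal, dtype=np.float64)
    psds = []
    weights = []
    freqs = None
    for onset, offset in non_vocal_segments:
        i0, i1 = int(round(onset * rate_hz)), int(round(offset * rate_hz))
        seg = demod_signal[max(i0, 0) : min(i1, demod_signal.size)]
        if seg.size < 2 * nperseg:
            continue
        f, psd = sp_signal.welch(seg, fs=rate_hz, window="hann", nperseg=nperseg)
        psds.append(psd)
        weights.append(seg.size)
        freqs = f
    if not psds:
        raise ValueError("no usable non-vocal segments")
    psd = np.average(np.vstack(psds), axis=0, weights=weights)
    m = freqs <= f_max_hz
    p_lin = float(np.trapezoid(psd[m], freqs[m]))
    return NoiseEstimate(10.0 * np.log10(p_lin), p_lin, f_max_hz)
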