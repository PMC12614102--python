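"""Shared-clock timeline arithmetic and sub-frame phase binning.

Audio and video triggers derive from one base clock by integer division
(200 MHz / 2^13 = 24.414 kHz audio; a further / 2^9 gives the 47.684 Hz
video frame rate, i.e. 512 audio samples per frame).  Because wing flapping
(26-30 Hz) is faster than the video Nyquist frequency, exposure onsets are
time-stamped against the flap dips of the transmitter signal: the lag
between exposure onset and dip minimum assigns each event frame to one of
eight flap-cycle phase bins, multiplying the camera's effective temporal
resolution.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from fractions import Fraction
from typing import Iterable, Sequence

import numpy as np

from fmtelem.events import WingFlapEvent

__all__ = ["ClockPlan", "FrameStamp", "clock_plan", "timestamp_frames", "assign_phase_bins"]


@dataclass(frozen=True)
class ClockPlan:
    """Exact (rational) trigger rates derived from one base clock."""

    base_hz: Fraction
    audio_div: int
    video_div: int

    @property
    def audio_rate(self) -> Fraction:
        return self.base_hz / self.audio_div

    @property
    def video_rate(self) -> Fraction:
        return self.audio_rate / self.video_div

    @property
    def audio_rate_hz(self) -> float:
        return float(self.audio_rate)

    @property
    def video_rate_hz(self) -> float:
        return float(self.video_rate)

    @property
    def samples_per_frame(self) -> int:
        # audio samples per video frame; exact by construction
        return self.video_div

    @property
    def frame_period(self) -> Fraction:
        return 1 / self.video_rate

    def duration_of_frames(self, n_frames: int) -> float:
        """Seconds spanned by ``n_frames`` video frames."""
        return float(n_frames * self.frame_period)


def clock_plan(base_hz: float = 2e8, audio_div: int = 2**13, video_div: int = 2**9) -> ClockPlan:
    if base_hz <= 0 or audio_div < 1 or video_div < 1:
        raise ValueError("base clock and divisors must be positive")
    return ClockPlan(Fraction(base_hz).limit_denominator(10**9), int(audio_div), int(video_div))


@dataclass
class FrameStamp:
    """One video exposure, optionally time-stamped against a flap event."""

    frame_index: int
    exposure_onset_s: float
    exposure_s: float = 0.003
    lag_s: float | None = None
    bin: int | None = None
    role: str | None = None  # 'first' | 'second'
    event_index: int | None = None


def timestamp_frames(plan: ClockPlan, duration_s: float, exposure_s: float = 0.003) -> list[FrameStamp]:
    """Exposure-onset skeleton for all frames in ``[0, duration_s)``.

    The first onset is at t = 0 by convention; onsets are spaced exactly one
    frame period apart (computed in rational arithmetic, so the timeline is
    gapless and strictly increasing).
    """
    if duration_s <= 0:
        raise ValueError("duration must be positive")
    period = plan.frame_period
    frames = []
    k = 0
    while True:
        onset = k * period
        if onset >= duration_s:
            break
        frames.append(FrameStamp(k, float(onset), exposure_s))
        k += 1
    return frames


def assign_phase_bins(
    events: Iterable[WingFlapEvent],
    frames: Sequence[FrameStamp],
    plan: ClockPlan,
    n_bins: int = 8,
) -> tuple[list[FrameStamp], int]:
    """Time-stamp event frames against flap dips and bin them by phase.

    For every valid event, the frame whose exposure onset is nearest the dip
    minimum becomes the first event frame and the subsequent frame the
    second.  The time stamp is ``lag = exposure_onset - dip_time``; the bin
    is ``floor(n_bins * (lag mod frame_period) / frame_period)``.

    Returns the stamped frames (new objects) and the number of events
    skipped because they fell outside the frame timeline.
    """
    if n_bins < 1:
        raise ValueError("n_bins must be >= 1")
    period = float(plan.frame_period)
    onsets = np.array([f.exposure_onset_s for f in frames])
    stamped: list[FrameStamp] = []
    skipped = 0
    for ev_idx, ev in enumerate(events):
        if not ev.valid:
            continue
        t = ev.dip_time_s
        if onsets.size == 0 or t < onsets[0] - period or t > onsets[-1] + period:
            skipped += 1
            continue
        nearest = int(np.argmin(np.abs(onsets - t)))
        for role, idx in (("first", nearest), ("second", nearest + 1)):
            if idx >= len(frames):
                continue
            base = frames[idx]
            lag = base.exposure_onset_s - t
            frac = (lag % period) / period
            stamped.append(
                FrameStamp(
                    frame_index=base.frame_index,
                    exposure_onset_s=base.exposure_onset_s,
                    exposure_s=base.exposure_s,
                    lag_s=lag,
                    bin=min(int(np.floor(n_bins * frac)), n_bins - 1),
                    role=role,
                    event_index=ev_idx,
                )
            )
    return stamped, skipped
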