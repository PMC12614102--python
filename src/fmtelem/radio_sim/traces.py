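"""Ground-truth accelerometer traces with annotated behavioral events.

The accelerometer picks up vocal vibrations (harmonic stacks up to ~7 kHz).
Wing flaps and proximity events, in contrast, modulate the radio carrier
directly (they appear even with the accelerometer short-circuited), so they
are synthesized as a separate carrier-frequency excursion waveform carried
alongside the acceleration samples.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "Annotation",
    "VocalEvent",
    "VocalSpec",
    "FlapBout",
    "ProximityEvent",
    "MovementSpec",
    "AccelerationTrace",
    "synthesize_accel_trace",
]


@dataclass(frozen=True)
class Annotation:
    """Ground-truth event: ``label`` is one of 'vocal', 'flap', 'proximity'."""

    onset_s: float
    offset_s: float
    label: str

    @property
    def center_s(self) -> float:
        return 0.5 * (self.onset_s + self.offset_s)


@dataclass(frozen=True)
class VocalEvent:
    """One deterministic vocalization: a harmonic stack at ``f0_hz``."""

    onset_s: float
    duration_s: float
    f0_hz: float
    amplitude_g: float
    harmonics: int = 1


@dataclass(frozen=True)
class VocalSpec:
    """Vocal content: explicit events plus an optional random event rate."""

    events: tuple[VocalEvent, ...] = ()
    rate_hz: float = 0.0
    f0_range_hz: tuple[float, float] = (500.0, 2500.0)
    duration_range_s: tuple[float, float] = (0.05, 0.2)
    amplitude_range_g: tuple[float, float] = (0.1, 0.68)
    max_harmonics: int = 2
    max_freq_hz: float = 7e3

    def validate(self) -> None:
        if self.rate_hz < 0:
            raise ValueError("vocal event rate must be non-negative")
        for ev in self.events:
            if ev.duration_s <= 0 or ev.f0_hz <= 0 or ev.amplitude_g < 0:
                raise ValueError(f"nonphysical vocal event: {ev}")
            if ev.harmonics < 1:
                raise ValueError("harmonics must be >= 1")


@dataclass(frozen=True)
class FlapBout:
    """A bout of continuous wing flapping."""

    onset_s: float
    duration_s: float


@dataclass(frozen=True)
class ProximityEvent:
    """A large carrier excursion (pecking/preening near the coil)."""

    onset_s: float
    duration_s: float
    amplitude_hz: float


@dataclass(frozen=True)
class MovementSpec:
    """Movement-driven carrier excursions: wing-flap dip trains and proximity bumps."""

    flap_bouts: tuple[FlapBout, ...] = ()
    flap_rate_hz: float = 28.0
    flap_depth_hz: float = 3e5
    flap_width_s: float = 0.008
    proximity_events: tuple[ProximityEvent, ...] = ()

    def validate(self) -> None:
        if self.flap_rate_hz <= 0 or self.flap_depth_hz < 0 or self.flap_width_s <= 0:
            raise ValueError("nonphysical flap parameters")
        for b in self.flap_bouts:
            if b.duration_s <= 0:
                raise ValueError("flap bout duration must be positive")
        for p in self.proximity_events:
            if p.duration_s <= 0 or p.amplitude_hz < 0:
                raise ValueError("nonphysical proximity event")


@dataclass
class AccelerationTrace:
    """Transmitter-side ground truth.

    ``samples`` is the acceleration waveform in g at ``rate_hz``;
    ``excursions_hz`` the co-sampled carrier-frequency excursion waveform
    (Hz) caused by movement; ``annotations`` the ground-truth event list.
    """

    samples: np.ndarray
    rate_hz: float
    annotations: list[Annotation] = field(default_factory=list)
    excursions_hz: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=np.float64)
        if self.rate_hz <= 0:
            raise ValueError("rate must be positive")
        if not np.all(np.isfinite(self.samples)):
            raise ValueError("acceleration samples must be finite")
        dur = self.duration_s
        for ann in self.annotations:
            if not (0.0 <= ann.onset_s <= ann.offset_s <= dur + 1e-9):
                raise ValueError(f"annotation outside [0, duration]: {ann}")

    @property
    def duration_s(self) -> float:
        return self.samples.size / self.rate_hz

    @property
    def t(self) -> np.ndarray:
        return np.arange(self.samples.size) / self.rate_hz


def _raised_cosine(t: np.ndarray, center: float, width: float) -> np.ndarray:
    """Unit-peak raised-cosine pulse supported on [center-width/2, center+width/2]."""
    x = (t - center) / width
    out = np.zeros_like(t)
    m = np.abs(x) < 0.5
    out[m] = 0.5 * (1.0 + np.cos(2.0 * np.pi * x[m]))
    return out


def synthesize_accel_trace(
    duration_s: float,
    vocal_spec: VocalSpec | None = None,
    movement_spec: MovementSpec | None = None,
    rate_hz: float = 31250.0,
    seed: int = 0,
) -> AccelerationTrace:
    """Build an annotated ground-truth trace.

    Parameters
    ----------
    duration_s:
        Trace duration; must be positive.
    vocal_spec:
        Harmonic-stack vocalizations written into the acceleration samples.
    movement_spec:
        Flap-dip trains and proximity bumps written into the carrier
        excursion waveform (``excursions_hz``), not the acceleration.
    rate_hz:
        Sample rate; must be at least twice the highest vocal frequency.
    seed:
        Seed for randomly placed vocal events; identical seeds give
        bit-identical traces.
    """
    if duration_s <= 0:
        raise ValueError("duration must be positive")
    if rate_hz <= 0:
        raise ValueError("rate must be positive")
    n = int(round(duration_s * rate_hz))
    t = np.arange(n) / rate_hz
    samples = np.zeros(n)
    excursions = np.zeros(n)
    annotations: list[Annotation] = []
    rng = np.random.default_rng(seed)

    if vocal_spec is not None:
        vocal_spec.validate()
        events = list(vocal_spec.events)
        if vocal_spec.rate_hz > 0:
            n_ev = rng.poisson(vocal_spec.rate_hz * duration_s)
            for _ in range(n_ev):
                dur = rng.uniform(*vocal_spec.duration_range_s)
                onset = rng.uniform(0.0, max(duration_s - dur, 0.0))
                f0 = rng.uniform(*vocal_spec.f0_range_hz)
                amp = rng.uniform(*vocal_spec.amplitude_range_g)
                nh = int(rng.integers(1, vocal_spec.max_harmonics + 1))
                events.append(VocalEvent(onset, dur, f0, amp, nh))
        for ev in events:
            if ev.f0_hz * ev.harmonics > vocal_spec.max_freq_hz:
                raise ValueError(
                    f"vocal harmonic {ev.f0_hz * ev.harmonics:.0f} Hz exceeds the "
                    f"{vocal_spec.max_freq_hz:.0f} Hz band limit"
                )
            if ev.f0_hz * ev.harmonics > rate_hz / 2:
                raise ValueError("vocal content exceeds the trace Nyquist frequency")
            i0 = int(round(ev.onset_s * rate_hz))
            i1 = min(int(round((ev.onset_s + ev.duration_s) * rate_hz)), n)
            if i1 <= i0:
                continue
            tt = t[i0:i1] - ev.onset_s
            wave = np.zeros(i1 - i0)
            for k in range(1, ev.harmonics + 1):
                wave += np.sin(2.0 * np.pi * k * ev.f0_hz * tt) / k
            peak = np.max(np.abs(wave))
            if peak > 0:
                wave *= ev.amplitude_g / peak
            # 5 ms cosine on/off ramps against spectral clicks
            ramp_n = min(int(0.005 * rate_hz), wave.size // 2)
            if ramp_n > 0:
                ramp = 0.5 * (1.0 - np.cos(np.pi * np.arange(ramp_n) / ramp_n))
                wave[:ramp_n] *= ramp
                wave[-ramp_n:] *= ramp[::-1]
            samples[i0:i1] += wave
            annotations.append(
                Annotation(ev.onset_s, min(ev.onset_s + ev.duration_s, duration_s), "vocal")
            )

    if movement_spec is not None:
        movement_spec.validate()
        w = movement_spec.flap_width_s
        for bout in movement_spec.flap_bouts:
            period = 1.0 / movement_spec.flap_rate_hz
            k = 0
            while True:
                center = bout.onset_s + (k + 0.5) * period
                if center + w / 2 > min(bout.onset_s + bout.duration_s, duration_s):
                    break
                excursions -= movement_spec.flap_depth_hz * _raised_cosine(t, center, w)
                annotations.append(Annotation(center - w / 2, center + w / 2, "flap"))
                k += 1
        for pe in movement_spec.proximity_events:
            center = pe.onset_s + pe.duration_s / 2
            excursions += pe.amplitude_hz * _raised_cosine(t, center, pe.duration_s)
            annotations.append(
                Annotation(pe.onset_s, min(pe.onset_s + pe.duration_s, duration_s), "proximity")
            )

    annotations.sort(key=lambda a: a.onset_s)
    return AccelerationTrace(samples, rate_hz, annotations, excursions)
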