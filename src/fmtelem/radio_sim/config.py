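"""Structured-text simulator configuration and end-to-end scenario driver."""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any

import numpy as np
import yaml

from fmtelem.presets import PRESETS, Preset
from fmtelem.radio_sim.channel import ChannelRealization, make_fading_scenario
from fmtelem.radio_sim.render import IntermediateSignalSet, render_antennas
from fmtelem.radio_sim.traces import (
    AccelerationTrace,
    FlapBout,
    MovementSpec,
    ProximityEvent,
    VocalEvent,
    VocalSpec,
    synthesize_accel_trace,
)
from fmtelem.radio_sim.transmitter import TransmitterSpec, fm_encode

__all__ = ["SimConfig", "TransmitterConfig", "load_sim_config", "run_simulation"]


@dataclass
class TransmitterConfig:
    name: str
    spec: TransmitterSpec
    vocal: VocalSpec | None = None
    movement: MovementSpec | None = None


@dataclass
class SimConfig:
    duration_s: float
    transmitters: list[TransmitterConfig]
    preset: str = "desk"
    seed: int = 0
    rate_hz: float | None = None
    lo_hz: float | None = None
    channel_kind: str = "constant"  # 'constant' | 'fading'
    amplitudes: tuple[float, float, float, float] = (1.0, 1.0, 1.0, 1.0)
    phases_rad: tuple[float, float, float, float] = (0.0, 0.0, 0.0, 0.0)
    noise_sigma: float = 0.0

    def resolved_rates(self, preset: Preset | None = None) -> tuple[float, float]:
        p = preset or PRESETS[self.preset]
        return (self.rate_hz or p.rate_hz, self.lo_hz or p.lo_hz)


def _vocal_from_dict(d: dict[str, Any] | None) -> VocalSpec | None:
    if not d:
        return None
    events = tuple(
        VocalEvent(
            float(e["onset_s"]),
            float(e["duration_s"]),
            float(e["f0_hz"]),
            float(e["amplitude_g"]),
            int(e.get("harmonics", 1)),
        )
        for e in d.get("events", [])
    )
    return VocalSpec(events=events, rate_hz=float(d.get("rate_hz", 0.0)))


def _movement_from_dict(d: dict[str, Any] | None) -> MovementSpec | None:
    if not d:
        return None
    flap = d.get("flap", {})
    bouts = tuple(
        FlapBout(float(b["onset_s"]), float(b["duration_s"])) for b in flap.get("bouts", [])
    )
    prox = tuple(
        ProximityEvent(float(p["onset_s"]), float(p["duration_s"]), float(p["amplitude_hz"]))
        for p in d.get("proximity", [])
    )
    return MovementSpec(
        flap_bouts=bouts,
        flap_rate_hz=float(flap.get("rate_hz", 28.0)),
        flap_depth_hz=float(flap.get("depth_hz", 3e5)),
        flap_width_s=float(flap.get("width_s", 0.008)),
        proximity_events=prox,
    )


def load_sim_config(path: str) -> SimConfig:
    """Parse a YAML simulator config (see README for the schema)."""
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    transmitters = []
    for td in raw.get("transmitters", []):
        spec = TransmitterSpec(
            carrier_hz=float(td["carrier_hz"]),
            sensitivity_hz_per_g=float(td.get("sensitivity_hz_per_g", 5e3)),
            hardware_highpass_hz=float(td.get("highpass_hz", 15.0)),
            drift_hz_per_s=float(td.get("drift_hz_per_s", 0.0)),
        )
        transmitters.append(
            TransmitterConfig(
                name=str(td.get("name", f"tx{len(transmitters) + 1}")),
                spec=spec,
                vocal=_vocal_from_dict(td.get("vocal")),
                movement=_movement_from_dict(td.get("movement")),
            )
        )
    if not transmitters:
        raise ValueError("config must define at least one transmitter")
    ch = raw.get("channel", {})
    return SimConfig(
        duration_s=float(raw["duration_s"]),
        transmitters=transmitters,
        preset=str(raw.get("preset", "desk")),
        seed=int(raw.get("seed", 0)),
        rate_hz=float(raw["rate_hz"]) if "rate_hz" in raw else None,
        lo_hz=float(raw["lo_hz"]) if "lo_hz" in raw else None,
        channel_kind=str(ch.get("kind", "constant")),
        amplitudes=tuple(float(x) for x in ch.get("amplitudes", (1, 1, 1, 1))),
        phases_rad=tuple(float(x) for x in ch.get("phases_rad", (0, 0, 0, 0))),
        noise_sigma=float(ch.get("noise_sigma", 0.0)),
    )


def run_simulation(
    cfg: SimConfig,
    seed: int | None = None,
    preset: str | None = None,
) -> tuple[IntermediateSignalSet, dict[str, Any]]:
    """Synthesize, encode and render every transmitter in a config.

    Transmitter tones are rendered noiselessly, summed, and the receiver
    noise is added once at the end so that per-antenna noise power is
    independent of the number of transmitters.  Returns the signal set and
    a ground-truth dict suitable for :func:`fmtelem.radio_sim.write_signals`.
    """
    seed = cfg.seed if seed is None else seed
    p = PRESETS[preset or cfg.preset]
    rate_hz, lo_hz = cfg.resolved_rates(p)
    band = (lo_hz - rate_hz / 2, lo_hz + rate_hz / 2)

    if cfg.channel_kind == "fading":
        channel = make_fading_scenario(cfg.duration_s, seed=seed, noise_sigma=cfg.noise_sigma)
    else:
        channel = ChannelRealization.constant(
            cfg.amplitudes, cfg.phases_rad, cfg.noise_sigma, cfg.duration_s, seed=seed
        )
    quiet = ChannelRealization(
        channel.times_s, channel.amplitudes, channel.phases, np.zeros(4), seed=seed
    )

    z_sum = None
    gt: dict[str, Any] = {"omega_t": {}, "carriers_hz": {}, "fade_intervals": channel.fade_intervals}
    traces: dict[str, AccelerationTrace] = {}
    for k, tx in enumerate(cfg.transmitters):
        trace = synthesize_accel_trace(
            cfg.duration_s, tx.vocal, tx.movement, rate_hz=rate_hz, seed=seed + 1000 * (k + 1)
        )
        omega_t = fm_encode(trace, tx.spec, band_hz=band)
        rendered = render_antennas(omega_t, quiet, lo_hz, rate_hz, seed=seed)
        z_sum = rendered.z if z_sum is None else z_sum + rendered.z
        gt["omega_t"][tx.name] = omega_t
        gt["carriers_hz"][tx.name] = tx.spec.carrier_hz
        traces[tx.name] = trace
    gt["trace"] = traces[cfg.transmitters[0].name]
    gt["traces"] = traces

    rng = np.random.default_rng(seed)
    for a in range(4):
        sigma = channel.noise_sigma[a]
        if sigma > 0:
            scale = sigma / np.sqrt(2.0)
            z_sum[a] += scale * rng.standard_normal(z_sum.shape[1])
            z_sum[a] += 1j * scale * rng.standard_normal(z_sum.shape[1])
    return IntermediateSignalSet(z_sum, rate_hz, lo_hz), gt
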