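"""Shared fixtures: session-scoped simulations reused across test modules."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pytest

from fmtelem.demod import DemodConfig, DemodOutput, demodulated_signal, run_demodulator
from fmtelem.presets import PRESETS, Preset
from fmtelem.radio_sim import (
    ChannelRealization,
    TransmitterSpec,
    VocalEvent,
    VocalSpec,
    fm_encode,
    hardware_filtered,
    make_fading_scenario,
    render_antennas,
    synthesize_accel_trace,
)

DESK: Preset = PRESETS["desk"]


@dataclass
class SimRun:
    signals: object
    out: DemodOutput
    cfg: DemodConfig
    extras: dict


@pytest.fixture(scope="session")
def desk() -> Preset:
    return DESK


@pytest.fixture(scope="session")
def diversity_run() -> SimRun:
    """Constant tone, equal antenna amplitudes, distinct phases, noise.

    Used for the diversity-gain and power-ratio checks: after compensation
    converges the combined signal power is 16x and the combined noise
    variance 4x a single antenna's.
    """
    dur = 3.0
    center = DESK.lo_hz
    omega_t = np.full(int(dur * DESK.rate_hz), center + 3e3)
    channel = ChannelRealization.constant(
        phases=(0.5, 2.0, -2.5, 1.0), noise_sigma=0.05, duration_s=dur
    )
    signals = render_antennas(omega_t, channel, DESK.lo_hz, DESK.rate_hz, seed=11)
    cfg = DemodConfig.from_preset("desk", center_hz=center)
    out = run_demodulator(signals, cfg)
    skip = int(0.5 * out.log_rate_hz)  # drop compensation/lock transients
    sources = {k: v[skip:] for k, v in out.baseband_sources().items()}
    return SimRun(signals, out, cfg, {"sources": sources, "skip": skip, "tone_hz": center + 3e3})


@pytest.fixture(scope="session")
def fading_run() -> SimRun:
    """Adversarial fading scenario with one deep fade per antenna."""
    dur = 4.0
    center = DESK.lo_hz
    channel = make_fading_scenario(dur, seed=5, noise_sigma=0.05)
    omega_t = np.full(int(dur * DESK.rate_hz), center + 3e3)
    signals = render_antennas(omega_t, channel, DESK.lo_hz, DESK.rate_hz, seed=12)
    cfg = DemodConfig.from_preset("desk", center_hz=center)
    out = run_demodulator(signals, cfg)
    return SimRun(signals, out, cfg, {"channel": channel, "tone_hz": center + 3e3})


@pytest.fixture(scope="session")
def vocal_tone_run() -> SimRun:
    """End-to-end 600 Hz / 0.68 g vocal tone through sim + demod."""
    dur = 2.0
    center = DESK.lo_hz
    trace = synthesize_accel_trace(
        dur,
        VocalSpec(events=(VocalEvent(0.5, 1.0, 600.0, 0.68),)),
        rate_hz=DESK.rate_hz,
        seed=2,
    )
    spec = TransmitterSpec(carrier_hz=center)
    omega_t = fm_encode(trace, spec)
    channel = ChannelRealization.constant(
        phases=(0.3, -1.0, 2.0, 0.8), noise_sigma=0.005, duration_s=dur
    )
    signals = render_antennas(omega_t, channel, DESK.lo_hz, DESK.rate_hz, seed=3)
    cfg = DemodConfig.from_preset("desk", center_hz=center)
    out = run_demodulator(signals, cfg)
    demod = demodulated_signal(out.omega, out.log_rate_hz)
    gt_full = spec.sensitivity_hz_per_g * hardware_filtered(trace, spec)
    step = int(DESK.rate_hz // out.log_rate_hz)
    gt_log = gt_full[::step][: out.omega.size]
    return SimRun(
        signals, out, cfg, {"trace": trace, "spec": spec, "demod": demod, "gt_log": gt_log}
    )


@pytest.fixture(scope="session")
def drift_run() -> SimRun:
    """800 kHz linear carrier drift across a 2 s trace, wide-band config."""
    rate, dur = 4e6, 2.0
    lo = DESK.lo_hz
    trace = synthesize_accel_trace(dur, rate_hz=rate, seed=5)
    spec = TransmitterSpec(carrier_hz=lo - 4e5, drift_hz_per_s=4e5)
    omega_t = fm_encode(trace, spec)
    signals = render_antennas(
        omega_t, ChannelRealization.constant(duration_s=dur), lo, rate, seed=6
    )
    cfg = DemodConfig.from_preset(
        "desk", center_hz=lo - 4e5, limit_hz=1e6, decimation=8, log_decimation=16
    )
    out = run_demodulator(signals, cfg)
    resid = demodulated_signal(out.omega, out.log_rate_hz)
    return SimRun(signals, out, cfg, {"residual": resid})


@pytest.fixture(scope="session")
def pinning_run() -> SimRun:
    """Transmitter commanded out of the limiting range for t in [0.8, 1.2] s."""
    dur = 2.0
    center = DESK.lo_hz
    n = int(dur * DESK.rate_hz)
    omega_t = np.full(n, float(center))
    lo_i, hi_i = int(0.8 * DESK.rate_hz), int(1.2 * DESK.rate_hz)
    cfg = DemodConfig.from_preset("desk", center_hz=center)
    omega_t[lo_i:hi_i] = center + 2 * cfg.limit_hz
    channel = ChannelRealization.constant(duration_s=dur)
    signals = render_antennas(omega_t, channel, DESK.lo_hz, DESK.rate_hz, seed=7)
    out = run_demodulator(signals, cfg)
    return SimRun(signals, out, cfg, {"window": (0.8, 1.2)})
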