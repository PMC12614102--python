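"""FM encoding of acceleration onto an instantaneous carrier frequency.

The transmitter frequency is ``omega_T(t) = omega_c(t) + c * a(t)`` where the
carrier ``omega_c`` may drift slowly, ``c`` is the end-to-end FM sensitivity
(5 kHz/g measured on hardware), and the acceleration passes a transmitter-side
first-order high-pass (15 Hz cutoff).  Movement excursions (flap dips,
proximity bumps) enter the carrier term directly.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal

from fmtelem.radio_sim.traces import AccelerationTrace

__all__ = ["TransmitterSpec", "fm_encode", "hardware_filtered"]


@dataclass(frozen=True)
class TransmitterSpec:
    carrier_hz: float
    sensitivity_hz_per_g: float = 5e3
    hardware_highpass_hz: float = 15.0
    drift_hz_per_s: float = 0.0

    def __post_init__(self) -> None:
        if self.sensitivity_hz_per_g <= 0:
            raise ValueError("FM sensitivity must be positive")
        if self.hardware_highpass_hz < 0:
            raise ValueError("high-pass cutoff must be non-negative")


def hardware_filtered(trace: AccelerationTrace, spec: TransmitterSpec) -> np.ndarray:
    """The acceleration after the transmitter's causal first-order high-pass.

    This is the reference waveform for the FM round trip: decoding
    ``(omega_T - carrier)/sensitivity`` recovers exactly this signal.
    """
    if spec.hardware_highpass_hz == 0:
        return trace.samples.copy()
    sos = signal.butter(1, spec.hardware_highpass_hz, "highpass", fs=trace.rate_hz, output="sos")
    return signal.sosfilt(sos, trace.samples)


def fm_encode(
    trace: AccelerationTrace,
    spec: TransmitterSpec,
    excursions: np.ndarray | None = None,
    band_hz: tuple[float, float] | None = None,
) -> np.ndarray:
    """Encode a trace as an instantaneous-frequency trajectory (Hz, at trace rate).

    Parameters
    ----------
    trace:
        Ground-truth acceleration.  Its rate must be at least twice the
        highest vocal frequency (enforced upstream at synthesis).
    spec:
        Carrier, sensitivity, transmitter high-pass and drift.
    excursions:
        Optional carrier-frequency excursion waveform (Hz); defaults to
        ``trace.excursions_hz``.  Pass an explicit zero array to suppress.
    band_hz:
        Optional ``(low, high)`` limits of the simulated intermediate band;
        if given, a trajectory leaving the band raises with the offending
        time.
    """
    if excursions is None:
        excursions = trace.excursions_hz
    omega = np.full(trace.samples.size, float(spec.carrier_hz))
    if spec.drift_hz_per_s != 0.0:
        omega += spec.drift_hz_per_s * trace.t
    omega += spec.sensitivity_hz_per_g * hardware_filtered(trace, spec)
    if excursions is not None:
        exc = np.asarray(excursions, dtype=np.float64)
        if exc.size != omega.size:
            raise ValueError("excursion waveform length does not match the trace")
        omega += exc
    if band_hz is not None:
        low, high = band_hz
        bad = np.flatnonzero((omega < low) | (omega > high))
        if bad.size:
            t_bad = bad[0] / trace.rate_hz
            raise ValueError(
                f"transmitter frequency leaves the intermediate band "
                f"[{low:.0f}, {high:.0f}] Hz at t = {t_bad:.6f} s "
                f"(omega_T = {omega[bad[0]]:.0f} Hz)"
            )
    return omega
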