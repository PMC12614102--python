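"""PLL demodulation driven by the phase of the summed baseband vector.

The four antenna streams are down-converted on a common tracking NCO with
per-antenna compensation phases, summed into the main vector, and the main
vector's unwrapped phase drives a PID that steers the tracking frequency.
Compensation phases are updated once per block from the block-mean rotated
vectors, driving the per-antenna residual angles to zero so the antennas sum
constructively.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import signal

from fmtelem.demod._kernels import ddc_loop, pll_loop
from fmtelem.demod.config import DemodConfig
from fmtelem.demod.filters import DecimatorDesign, design_decimator
from fmtelem.radio_sim.render import IntermediateSignalSet

__all__ = [
    "DemodOutput",
    "LossInterval",
    "ddc",
    "run_demodulator",
    "detect_tracking_loss",
    "demodulated_signal",
]

SOURCES = ("A", "B", "C", "D", "M")


@dataclass
class DemodOutput:
    """Demodulator result.

    ``omega`` is the tracking frequency (absolute Hz) and ``theta`` the
    unwrapped main-vector phase, both at ``log_rate_hz``; ``u`` holds the
    per-antenna compensated baseband vectors at the same instants (their sum
    is the main vector).  ``alpha``/``dphi`` are the per-antenna residual and
    compensation phases at ``block_rate_hz``; ``r_block_mean`` /
    ``r_block_power`` the per-block first and second moments of the rotated
    vectors for sources A-D and M (row 4).
    """

    omega: np.ndarray
    theta: np.ndarray
    lock: np.ndarray
    u: np.ndarray
    alpha: np.ndarray
    dphi: np.ndarray
    r_block_mean: np.ndarray
    r_block_power: np.ndarray
    log_rate_hz: float
    block_rate_hz: float
    center_hz: float
    limit_hz: float
    lo_hz: float
    config: DemodConfig | None = field(default=None, repr=False)

    @property
    def t(self) -> np.ndarray:
        return np.arange(self.omega.size) / self.log_rate_hz

    @property
    def duration_s(self) -> float:
        return self.omega.size / self.log_rate_hz

    def baseband_sources(self) -> dict[str, np.ndarray]:
        """Compensated baseband vectors per source, with M the antenna sum."""
        out = {name: self.u[i] for i, name in enumerate(SOURCES[:4])}
        out["M"] = self.u.sum(axis=0)
        return out


def ddc(
    z: np.ndarray,
    rate_hz: float,
    nco_freq_hz: float | np.ndarray,
    phase_offset: float = 0.0,
    decimation: int = 128,
    passband_hz: float = 1e5,
    stopband_hz: float | None = None,
    design: DecimatorDesign | None = None,
) -> np.ndarray:
    """Open-loop digital down-conversion of one complex stream.

    ``nco_freq_hz`` may be a scalar or a per-baseband-sample array (Hz,
    relative to the stream's zero frequency).  The output is
    ``decimate(lowpass(z * exp(-i*(phi_nco - phase_offset))))`` at rate
    ``rate_hz/decimation``.
    """
    z = np.ascontiguousarray(z, dtype=np.complex128)
    if not np.all(np.isfinite(z)):
        raise ValueError("input signal must be finite")
    if design is None:
        design = design_decimator(rate_hz, decimation, passband_hz, stopband_hz)
    n_bb = z.size // design.decimation
    freq = np.broadcast_to(np.asarray(nco_freq_hz, dtype=np.float64), (n_bb,))
    out = np.empty(n_bb, dtype=np.complex128)
    ddc_loop(
        z,
        float(rate_hz),
        design.h1,
        design.h2,
        design.d1,
        design.d2,
        np.ascontiguousarray(freq),
        float(phase_offset),
        out,
    )
    return out


def run_demodulator(
    signals: IntermediateSignalSet,
    cfg: DemodConfig,
    probe: np.ndarray | None = None,
) -> DemodOutput:
    """Demodulate one transmitter channel from a four-antenna signal set.

    ``probe`` optionally adds a per-baseband-sample excitation (Hz) to the
    controller output; it is used to measure the closed-loop transfer
    function.
    """
    z = signals.z
    if z.shape[0] != 4:
        raise ValueError("four antenna sequences are required")
    lo = signals.lo_hz
    band = signals.band_hz
    if not band[0] < cfg.center_hz < band[1]:
        raise ValueError(
            f"channel center {cfg.center_hz:.0f} Hz outside the simulated band {band}"
        )
    design = design_decimator(signals.rate_hz, cfg.decimation, cfg.passband_hz)
    f_bb = signals.rate_hz / cfg.decimation
    if cfg.limit_hz >= f_bb / 2 * cfg.decimation:  # conservative band-edge guard
        raise ValueError("limit range exceeds the simulated band")
    kp, ki, kd = cfg.gains(f_bb)

    n_bb = z.shape[1] // cfg.decimation
    n_log = (n_bb + cfg.log_decimation - 1) // cfg.log_decimation
    n_blk = n_bb // cfg.block
    if probe is None:
        probe = np.zeros(n_bb)
    else:
        probe = np.ascontiguousarray(probe, dtype=np.float64)
        if probe.size != n_bb:
            raise ValueError(f"probe must have one value per baseband sample ({n_bb})")

    omega_log = np.empty(n_log)
    theta_log = np.empty(n_log)
    lock_log = np.empty(n_log, dtype=np.bool_)
    u_log = np.empty((4, n_log), dtype=np.complex128)
    alpha_blk = np.empty((4, n_blk))
    dphi_blk = np.empty((4, n_blk))
    rmean_blk = np.empty((5, n_blk), dtype=np.complex128)
    rpow_blk = np.empty((5, n_blk))

    pll_loop(
        np.ascontiguousarray(z),
        float(signals.rate_hz),
        design.h1,
        design.h2,
        design.d1,
        design.d2,
        float(cfg.center_hz - lo),
        float(cfg.limit_hz),
        float(kp),
        float(ki),
        float(kd),
        float(cfg.gamma),
        int(cfg.block),
        float(cfg.unwrap_turns),
        int(cfg.log_decimation),
        probe,
        omega_log,
        theta_log,
        lock_log,
        u_log,
        alpha_blk,
        dphi_blk,
        rmean_blk,
        rpow_blk,
    )
    return DemodOutput(
        omega=omega_log + lo,
        theta=theta_log,
        lock=lock_log,
        u=u_log,
        alpha=alpha_blk,
        dphi=dphi_blk,
        r_block_mean=rmean_blk,
        r_block_power=rpow_blk,
        log_rate_hz=f_bb / cfg.log_decimation,
        block_rate_hz=f_bb / cfg.block,
        center_hz=cfg.center_hz,
        limit_hz=cfg.limit_hz,
        lo_hz=lo,
        config=cfg,
    )


@dataclass(frozen=True)
class LossInterval:
    onset_s: float
    offset_s: float


def detect_tracking_loss(
    omega: np.ndarray,
    rate_hz: float,
    center_hz: float,
    limit_hz: float,
) -> tuple[list[LossInterval], float]:
    """Maximal runs of ``|omega - center| >= limit`` and percent time lost.

    The comparison allows a 1e-6 Hz slack to absorb float rounding of the
    absolute-frequency bookkeeping.
    """
    omega = np.asarray(omega, dtype=np.float64)
    lost = np.abs(omega - center_hz) >= limit_hz - 1e-6
    if omega.size == 0:
        return [], 0.0
    edges = np.flatnonzero(np.diff(lost.astype(np.int8)))
    starts = list(edges[lost[edges + 1]] + 1)
    stops = list(edges[~lost[edges + 1]] + 1)
    if lost[0]:
        starts.insert(0, 0)
    if lost[-1]:
        stops.append(omega.size)
    intervals = [LossInterval(s / rate_hz, e / rate_hz) for s, e in zip(starts, stops)]
    percent = 100.0 * lost.sum() / omega.size
    return intervals, percent


def demodulated_signal(
    omega: np.ndarray,
    rate_hz: float,
    highpass_hz: float = 200.0,
    sensitivity_hz_per_g: float | None = None,
) -> np.ndarray:
    """High-pass filtered tracking frequency: the acceleration estimate.

    A zero-phase high-pass (4th-order Butterworth, default 200 Hz cutoff)
    removes carrier, drift and battery/temperature trends.  Returns Hz of
    frequency deviation, or g when a sensitivity is given.
    """
    omega = np.asarray(omega, dtype=np.float64)
    if highpass_hz <= 0:
        out = omega - omega.mean()
    else:
        sos = signal.butter(4, highpass_hz, "highpass", fs=rate_hz, output="sos")
        out = signal.sosfiltfilt(sos, omega)
    if sensitivity_hz_per_g is not None:
        out = out / sensitivity_hz_per_g
    return out
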