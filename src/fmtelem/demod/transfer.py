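"""Empirical closed-loop transfer function of the tracking PLL.

A white-noise probe is added to the control signal (the tracking frequency)
while the demodulator locks onto a clean constant-frequency tone.  The
probe-to-tracking-frequency transfer is the loop's sensitivity function S;
the closed-loop transmitter-to-tracking transfer is H = 1 - S, which for a
well-tuned loop has a low-pass characteristic.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy import signal as sp_signal

from fmtelem.demod.config import DemodConfig
from fmtelem.demod.loop import run_demodulator
from fmtelem.radio_sim.channel import ChannelRealization
from fmtelem.radio_sim.render import render_antennas

__all__ = ["TransferFunction", "measure_closed_loop"]


@dataclass
class TransferFunction:
    freq_hz: np.ndarray
    gain: np.ndarray  # |H| per frequency

    @property
    def bandwidth_3db_hz(self) -> float:
        """First frequency at which the gain falls below 1/sqrt(2)."""
        thresh = 1.0 / np.sqrt(2.0)
        below = np.flatnonzero(self.gain < thresh)
        if below.size == 0:
            return float(self.freq_hz[-1])
        i = below[0]
        if i == 0:
            return float(self.freq_hz[0])
        f0, f1 = self.freq_hz[i - 1], self.freq_hz[i]
        g0, g1 = self.gain[i - 1], self.gain[i]
        return float(f0 + (g0 - thresh) / (g0 - g1) * (f1 - f0))

    def octave_averaged(self, f_min: float) -> tuple[np.ndarray, np.ndarray]:
        """Geometric-mean frequencies and mean gains over octave bins."""
        fc, gains = [], []
        lo = max(f_min, self.freq_hz[1])
        while lo < self.freq_hz[-1]:
            hi = 2 * lo
            m = (self.freq_hz >= lo) & (self.freq_hz < hi)
            if m.any():
                fc.append(np.sqrt(lo * hi))
                gains.append(self.gain[m].mean())
            lo = hi
        return np.array(fc), np.array(gains)


def measure_closed_loop(
    cfg: DemodConfig,
    probe_level_hz: float,
    seed: int,
    rate_hz: float = 1e6,
    lo_hz: float = 300e6,
    duration_s: float = 2.0,
    nperseg: int = 4096,
) -> TransferFunction:
    """Measure |H(f)| of the PLL closed loop by white-noise probing.

    ``probe_level_hz`` is the standard deviation of the frequency probe per
    baseband sample; it must be positive and small relative to the limiting
    range so that the loop stays linear.
    """
    if probe_level_hz <= 0:
        raise ValueError("probe level must be positive (degenerate measurement)")
    cfg = replace(cfg, log_decimation=1)
    n = int(duration_s * rate_hz)
    omega_t = np.full(n, cfg.center_hz)
    channel = ChannelRealization.constant(duration_s=duration_s)
    signals = render_antennas(omega_t, channel, lo_hz, rate_hz, seed=seed)
    f_bb = rate_hz / cfg.decimation
    n_bb = n // cfg.decimation
    rng = np.random.default_rng(seed)
    probe = probe_level_hz * rng.standard_normal(n_bb)
    out = run_demodulator(signals, cfg, probe=probe)

    # drop the lock-in transient before estimating spectra
    skip = min(n_bb // 10, 4 * nperseg)
    resp = out.omega[skip:] - cfg.center_hz
    p = probe[skip:]
    f, s_pp = sp_signal.welch(p, fs=f_bb, nperseg=nperseg)
    _, s_py = sp_signal.csd(p, resp, fs=f_bb, nperseg=nperseg)
    sens = s_py / s_pp
    h = 1.0 - sens
    return TransferFunction(f[1:], np.abs(h)[1:])
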