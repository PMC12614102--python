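"""Unit and property tests for the PLL demodulator and DDC."""

import numpy as np
import pytest
from scipy import signal as sp_signal

from fmtelem.demod import (
    DemodConfig,
    ddc,
    demodulated_signal,
    design_decimator,
    detect_tracking_loss,
    measure_closed_loop,
    run_demodulator,
)
from fmtelem.presets import PRESETS
from fmtelem.radio_sim import (
    ChannelRealization,
    TransmitterSpec,
    render_antennas,
    synthesize_accel_trace,
)
from reference_demod import reference_demodulator

DESK = PRESETS["desk"]


def _tone_signals(offset_hz, duration_s=0.5, phases=(0, 0, 0, 0), amplitudes=(1, 1, 1, 1),
                  noise_sigma=0.0, seed=0, rate=DESK.rate_hz, lo=DESK.lo_hz):
    n = int(duration_s * rate)
    omega_t = np.full(n, lo + offset_hz)
    ch = ChannelRealization.constant(amplitudes, phases, noise_sigma, duration_s)
    return render_antennas(omega_t, ch, lo, rate, seed=seed)


class TestFilterDesign:
    def test_passband_ripple_and_stopband(self):
        design = design_decimator(DESK.rate_hz, DESK.decimation, DESK.passband_hz)
        # full cascade response at the intermediate rate
        h = design.h1
        if design.h2.size > 1 or design.h1.size > 1:
            h2_up = np.zeros((design.h2.size - 1) * design.d1 + 1)
            h2_up[:: design.d1] = design.h2
            h = np.convolve(design.h1, h2_up)
        w, resp = sp_signal.freqz(h, worN=8192, fs=design.rate_hz)
        gain_db = 20 * np.log10(np.maximum(np.abs(resp), 1e-12))
        passband = w <= design.passband_hz
        stopband = w >= design.baseband_rate_hz / 2
        assert np.max(np.abs(gain_db[passband])) <= 0.1
        assert np.max(gain_db[stopband]) <= -60.0

    def test_invalid_parameters(self):
        with pytest.raises(ValueError):
            design_decimator(1e6, 0, 1e3)
        with pytest.raises(ValueError):
            design_decimator(1e6, 4, 2e5)  # passband above decimated Nyquist


class TestDdc:
    RATE = 250e3

    def test_tone_at_nco_is_dc(self):
        n = 25_000
        t = np.arange(n) / self.RATE
        z = 0.7 * np.exp(1j * 2 * np.pi * 5e3 * t)
        u = ddc(z, self.RATE, 5e3, decimation=4, passband_hz=20e3)
        tail = u[200:]
        assert np.max(np.abs(np.abs(tail) - 0.7)) < 0.7 * 0.012  # within 0.1 dB ripple
        assert np.max(np.abs(np.angle(tail / tail[0]))) < 1e-3

    def test_phase_offset_rotates_output(self):
        n = 25_000
        t = np.arange(n) / self.RATE
        z = np.exp(1j * 2 * np.pi * 5e3 * t)
        u0 = ddc(z, self.RATE, 5e3, phase_offset=0.0, decimation=4, passband_hz=20e3)
        u1 = ddc(z, self.RATE, 5e3, phase_offset=np.pi / 2, decimation=4, passband_hz=20e3)
        rot = np.angle(np.mean(u1[200:] / u0[200:]))
        assert rot == pytest.approx(np.pi / 2, abs=1e-9)

    def test_out_of_band_tone_attenuated_60db(self):
        # sharp design: stopband at 1.2x passband
        n = 250_000
        t = np.arange(n) / self.RATE
        kw = dict(decimation=4, passband_hz=25e3, stopband_hz=30e3)
        in_band = ddc(np.exp(1j * 2 * np.pi * 10e3 * t), self.RATE, 0.0, **kw)
        out_band = ddc(np.exp(1j * 2 * np.pi * 30e3 * t), self.RATE, 0.0, **kw)
        p_in = np.mean(np.abs(in_band[500:]) ** 2)
        p_out = np.mean(np.abs(out_band[500:]) ** 2)
        assert 10 * np.log10(p_in / p_out) >= 60.0

    def test_nonfinite_input_rejected(self):
        z = np.ones(1000, dtype=complex)
        z[10] = np.nan
        with pytest.raises(ValueError, match="finite"):
            ddc(z, self.RATE, 0.0, decimation=4, passband_hz=20e3)


class TestRunDemodulator:
    def test_converges_to_tone(self):
        signals = _tone_signals(10e3, duration_s=0.5)
        cfg = DemodConfig.from_preset("desk", center_hz=DESK.lo_hz)
        out = run_demodulator(signals, cfg)
        half = out.omega.size // 2
        err = out.omega[half:] - (DESK.lo_hz + 10e3)
        assert np.max(np.abs(err)) < 1.0
        assert np.max(np.abs(out.alpha[:, -1])) < 1e-2
        u_m = np.abs(out.u.sum(axis=0))
        assert u_m[-1] == pytest.approx(4.0, rel=1e-3)  # 4x single-antenna amplitude
        assert out.lock.all()

    def test_phase_compensation_recovers_destructive_sum(self):
        phases = (0.0, np.pi / 2, np.pi, 3 * np.pi / 2)
        signals = _tone_signals(5e3, duration_s=1.0, phases=phases)
        on = run_demodulator(signals, DemodConfig.from_preset("desk", center_hz=DESK.lo_hz))
        off = run_demodulator(
            signals, DemodConfig.from_preset("desk", center_hz=DESK.lo_hz, gamma=0.0)
        )
        u_on = np.abs(on.u.sum(axis=0))[-1]
        u_off = np.abs(off.u.sum(axis=0))[-1]
        assert u_on == pytest.approx(4.0, rel=1e-2)
        assert u_off < 1e-6

    def test_compensation_fixed_point(self):
        phases = (0.7, -2.1, 1.3, 2.9)
        signals = _tone_signals(2e3, duration_s=1.0, phases=phases, noise_sigma=0.01, seed=5)
        out = run_demodulator(signals, DemodConfig.from_preset("desk", center_hz=DESK.lo_hz))
        assert np.max(np.abs(out.alpha[:, -1])) < 1e-2

    def test_out_of_range_pins_and_unlocks(self, pinning_run):
        out = pinning_run.out
        cfg = pinning_run.cfg
        t0, t1 = pinning_run.extras["window"]
        assert np.max(np.abs(out.omega - cfg.center_hz)) <= cfg.limit_hz
        mid = (out.t > t0 + 0.05) & (out.t < t1 - 0.05)
        assert np.all(out.omega[mid] == cfg.center_hz + cfg.limit_hz)
        assert not out.lock[mid].any()
        # lock flag false exactly where |omega - center| >= limit
        lost = np.abs(out.omega - cfg.center_hz) >= cfg.limit_hz - 1e-6
        assert np.array_equal(~out.lock, lost)

    def test_center_outside_band_rejected(self):
        signals = _tone_signals(1e3, duration_s=0.05)
        cfg = DemodConfig.from_preset("desk", center_hz=DESK.lo_hz + DESK.rate_hz)
        with pytest.raises(ValueError, match="outside the simulated band"):
            run_demodulator(signals, cfg)

    def test_unwrap_handles_100_turn_ramps(self):
        # a weak proportional gain lets the error phase ramp through ~100
        # turns before the loop catches the 40 kHz offset
        for sign in (1, -1):
            signals = _tone_signals(sign * 40e3, duration_s=0.25, seed=2)
            cfg = DemodConfig.from_preset(
                "desk", center_hz=DESK.lo_hz, kp=395.0, ki=0.0, kd=0.0, log_decimation=1
            )
            out = run_demodulator(signals, cfg)
            turns = out.theta / (2 * np.pi)
            assert sign * turns.max() if sign > 0 else -turns.min() > 100.0
            assert np.max(np.abs(turns)) < cfg.unwrap_turns + 1e-9
            assert np.max(np.abs(np.diff(out.theta))) < np.pi

    def test_fading_robustness(self, fading_run):
        out = fading_run.out
        tone = fading_run.extras["tone_hz"]
        err = np.abs(out.omega - tone)
        for fade in fading_run.extras["channel"].fade_intervals:
            m = (out.t >= fade.onset_s) & (out.t <= fade.offset_s)
            assert np.max(err[m]) < 1e3, f"fade of antenna {fade.antenna}"

    def test_single_live_antenna_rsnr_penalty(self):
        # gains (1,0,0,0): M keeps the noise of all four antennas -> -6 dB
        from fmtelem.rsnr import rsnr_frames

        signals = _tone_signals(
            3e3, duration_s=2.0, amplitudes=(1, 0, 0, 0), noise_sigma=0.05, seed=8
        )
        out = run_demodulator(signals, DemodConfig.from_preset("desk", center_hz=DESK.lo_hz))
        skip = int(0.3 * out.log_rate_hz)
        sources = {k: v[skip:] for k, v in out.baseband_sources().items()}
        series = rsnr_frames(sources, DESK.frame_len, out.log_rate_hz)
        gain = np.mean(series.rsnr_db["M"] - series.rsnr_db["A"])
        assert gain == pytest.approx(-6.0, abs=0.5)

    def test_probe_length_validated(self):
        signals = _tone_signals(1e3, duration_s=0.05)
        cfg = DemodConfig.from_preset("desk", center_hz=DESK.lo_hz)
        with pytest.raises(ValueError, match="probe"):
            run_demodulator(signals, cfg, probe=np.zeros(7))


class TestEquivalenceOracle:
    def test_matches_straight_line_reference(self):
        n = 10_000
        rng = np.random.default_rng(0)
        omega_t = DESK.lo_hz + 3e3 + 500 * np.sin(2 * np.pi * 300 * np.arange(n) / DESK.rate_hz)
        ch = ChannelRealization.constant(
            phases=(0.3, -1.0, 2.0, 0.8), noise_sigma=0.05, duration_s=n / DESK.rate_hz
        )
        signals = render_antennas(omega_t, ch, DESK.lo_hz, DESK.rate_hz, seed=1)
        cfg = DemodConfig.from_preset(
            "desk", center_hz=DESK.lo_hz, block=64, log_decimation=4
        )
        out = run_demodulator(signals, cfg)
        design = design_decimator(DESK.rate_hz, cfg.decimation, cfg.passband_hz)
        f_bb = DESK.rate_hz / cfg.decimation
        kp, ki, kd = cfg.gains(f_bb)
        ref = reference_demodulator(
            signals.z, DESK.rate_hz, design.h1, design.h2, design.d1, design.d2,
            cfg.center_hz - DESK.lo_hz, cfg.limit_hz, kp, ki, kd, cfg.gamma,
            cfg.block, float(cfg.unwrap_turns), cfg.log_decimation,
            np.zeros(n // cfg.decimation),
        )
        # agreement to the last ulp of the compiled vs interpreted libm calls
        np.testing.assert_allclose(out.omega - DESK.lo_hz, ref["omega"], rtol=0, atol=1e-5)
        np.testing.assert_allclose(out.theta, ref["theta"], rtol=0, atol=1e-6)
        np.testing.assert_allclose(out.u, ref["u"], rtol=0, atol=1e-11)
        np.testing.assert_allclose(out.alpha, ref["alpha"], rtol=0, atol=1e-9)
        np.testing.assert_allclose(out.r_block_mean, ref["rmean"], rtol=0, atol=1e-11)
        np.testing.assert_allclose(out.r_block_power, ref["rpow"], rtol=0, atol=1e-11)
        assert np.array_equal(out.lock, ref["lock"])


class TestTrackingLoss:
    def test_no_loss(self):
        omega = np.full(1000, 5e6)
        intervals, pct = detect_tracking_loss(omega, 1000.0, 5e6, 1e5)
        assert intervals == [] and pct == 0.0

    def test_one_percent(self):
        rate = 1000.0
        omega = np.full(100_000, 5e6)
        omega[50_000:51_000] = 5e6 + 1e5  # 1 s of a 100 s trace at the limit
        intervals, pct = detect_tracking_loss(omega, rate, 5e6, 1e5)
        assert len(intervals) == 1
        assert pct == pytest.approx(1.0)
        assert intervals[0].onset_s == pytest.approx(50.0)
        assert intervals[0].offset_s == pytest.approx(51.0)

    def test_matches_commanded_window(self, pinning_run):
        out = pinning_run.out
        cfg = pinning_run.cfg
        t0, t1 = pinning_run.extras["window"]
        intervals, pct = detect_tracking_loss(
            out.omega, out.log_rate_hz, cfg.center_hz, cfg.limit_hz
        )
        assert len(intervals) == 1
        dt = 1.0 / out.log_rate_hz
        assert abs(intervals[0].onset_s - t0) <= dt
        # the offset additionally carries the deterministic phase-unwind
        # time of the loop: unwrap_turns / (frequency error at the limit)
        relock = cfg.unwrap_turns / cfg.limit_hz
        assert t1 - dt <= intervals[0].offset_s <= t1 + relock + dt


class TestDemodulatedSignal:
    def test_constant_omega_gives_zero(self):
        out = demodulated_signal(np.full(31_250, 3e8), 31_250.0)
        assert np.max(np.abs(out)) < 1e-3  # float residue of filtering a 3e8 Hz constant

    def test_end_to_end_tone_recovery(self, vocal_tone_run):
        lr = vocal_tone_run.out.log_rate_hz
        demod = vocal_tone_run.extras["demod"]
        gt = vocal_tone_run.extras["gt_log"]
        i0, i1 = int(0.6 * lr), int(1.4 * lr)
        corr = np.corrcoef(demod[i0:i1], gt[i0:i1])[0, 1]
        gain = np.dot(demod[i0:i1], gt[i0:i1]) / np.dot(gt[i0:i1], gt[i0:i1])
        assert corr > 0.99
        assert gain == pytest.approx(1.0, abs=0.05)  # 3.4 kHz deviation within 5%

    def test_linear_drift_removed(self, drift_run):
        resid = drift_run.extras["residual"]
        n = resid.size
        assert np.max(np.abs(resid[n // 10 : -n // 10])) < 1.0


@pytest.fixture(scope="module")
def default_tf():
    cfg = DemodConfig.from_preset("desk", center_hz=DESK.lo_hz)
    return measure_closed_loop(cfg, probe_level_hz=500.0, seed=3, duration_s=2.0)


class TestClosedLoopTransfer:
    def test_low_pass_characteristic(self, default_tf):
        f3db = default_tf.bandwidth_3db_hz
        assert f3db > 0
        _, gains = default_tf.octave_averaged(f3db)
        assert np.all(np.diff(gains) < 0)  # monotone decay above the -3 dB point

    def test_small_kp_lowers_bandwidth(self, default_tf):
        cfg = DemodConfig.from_preset(
            "desk", center_hz=DESK.lo_hz, kp=0.005 * 500e3, ki=0.0, kd=0.0
        )
        tf_small = measure_closed_loop(cfg, probe_level_hz=500.0, seed=3, duration_s=2.0)
        assert tf_small.bandwidth_3db_hz < default_tf.bandwidth_3db_hz

    def test_zero_probe_rejected(self):
        cfg = DemodConfig.from_preset("desk", center_hz=DESK.lo_hz)
        with pytest.raises(ValueError, match="probe"):
            measure_closed_loop(cfg, probe_level_hz=0.0, seed=0)


class TestConfigValidation:
    def test_gamma_range(self):
        with pytest.raises(ValueError):
            DemodConfig(center_hz=3e8, gamma=1.5)

    def test_block_positive(self):
        with pytest.raises(ValueError):
            DemodConfig(center_hz=3e8, block=0)
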