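"""Numba inner loops for the down-converters and the tracking PLL.

Arithmetic is plain double precision in a fixed order so that the pure-Python
reference implementation used in the tests can reproduce results exactly.
"""

import math

import numpy as np
from numba import njit

TWO_PI = 2.0 * math.pi


@njit(cache=True)
def ddc_loop(x, rate_hz, h1, h2, d1, d2, freq_bb, dphi, out):  # pragma: no cover - numba
    """Open-loop digital down-conversion of one channel.

    ``freq_bb`` holds the NCO frequency (Hz relative to the stream) per
    baseband output sample; ``dphi`` is a static phase offset *added* to the
    output phase (the NCO phase enters as ``exp(-i*(phi - dphi))``).
    """
    l1 = h1.shape[0]
    l2 = h2.shape[0]
    ring1 = np.zeros(l1, dtype=np.complex128)
    ring2 = np.zeros(l2, dtype=np.complex128)
    p1 = 0
    p2 = 0
    idx = 0
    phi = 0.0
    n_bb = out.shape[0]
    cd = complex(math.cos(dphi), math.sin(dphi))
    for nn in range(n_bb):
        f = freq_bb[nn]
        for j2 in range(d2):
            for j1 in range(d1):
                phi += TWO_PI * f / rate_hz
                while phi > math.pi:
                    phi -= TWO_PI
                while phi <= -math.pi:
                    phi += TWO_PI
                osc = complex(math.cos(phi), -math.sin(phi))
                ring1[p1] = (x[idx] * osc) * cd
                idx += 1
                p1 += 1
                if p1 == l1:
                    p1 = 0
            acc = complex(0.0, 0.0)
            q = p1 - 1
            for m in range(l1):
                if q < 0:
                    q += l1
                acc += h1[m] * ring1[q]
                q -= 1
            ring2[p2] = acc
            p2 += 1
            if p2 == l2:
                p2 = 0
        acc = complex(0.0, 0.0)
        q = p2 - 1
        for m in range(l2):
            if q < 0:
                q += l2
            acc += h2[m] * ring2[q]
            q -= 1
        out[nn] = acc


@njit(cache=True)
def pll_loop(  # pragma: no cover - numba
    z,
    rate_hz,
    h1,
    h2,
    d1,
    d2,
    omega0_rel,
    limit_hz,
    kp,
    ki,
    kd,
    gamma,
    block,
    max_turns,
    log_dec,
    probe,
    omega_log,
    theta_log,
    lock_log,
    u_log,
    alpha_blk,
    dphi_blk,
    rmean_blk,
    rpow_blk,
):
    """Closed-loop four-antenna PLL demodulation with phase compensation.

    Per baseband sample: mix/decimate all antennas on the common tracking
    NCO (with per-antenna compensation offsets), sum into the main vector,
    take its phase as the unwrapped error of a PID that steers the tracking
    frequency within ``omega0_rel +- limit_hz`` (conditional integration as
    anti-windup).  Every ``block`` samples the block-mean rotated vectors
    update the compensation phases by ``gamma * alpha``.
    """
    na = z.shape[0]
    d = d1 * d2
    n_bb = z.shape[1] // d
    f_bb = rate_hz / d
    l1 = h1.shape[0]
    l2 = h2.shape[0]
    ring1 = np.zeros((na, l1), dtype=np.complex128)
    ring2 = np.zeros((na, l2), dtype=np.complex128)
    u = np.zeros(na, dtype=np.complex128)
    dphi = np.zeros(na)
    comp = np.zeros(na, dtype=np.complex128)  # exp(-i*dphi)
    for a in range(na):
        comp[a] = complex(1.0, 0.0)
    racc = np.zeros(na + 1, dtype=np.complex128)
    racc2 = np.zeros(na + 1)
    p1 = 0
    p2 = 0
    idx = 0
    phi = 0.0
    f_track = omega0_rel
    theta_prev = 0.0
    theta_u = 0.0
    e_prev = 0.0
    integ = 0.0
    clamp = TWO_PI * max_turns
    n_blk = alpha_blk.shape[1]
    blk = 0
    for nn in range(n_bb):
        for j2 in range(d2):
            for j1 in range(d1):
                phi += TWO_PI * f_track / rate_hz
                while phi > math.pi:
                    phi -= TWO_PI
                while phi <= -math.pi:
                    phi += TWO_PI
                osc = complex(math.cos(phi), -math.sin(phi))
                for a in range(na):
                    ring1[a, p1] = (z[a, idx] * osc) * comp[a]
                idx += 1
                p1 += 1
                if p1 == l1:
                    p1 = 0
            for a in range(na):
                acc = complex(0.0, 0.0)
                q = p1 - 1
                for m in range(l1):
                    if q < 0:
                        q += l1
                    acc += h1[m] * ring1[a, q]
                    q -= 1
                ring2[a, p2] = acc
            p2 += 1
            if p2 == l2:
                p2 = 0
        u_m = complex(0.0, 0.0)
        for a in range(na):
            acc = complex(0.0, 0.0)
            q = p2 - 1
            for m in range(l2):
                if q < 0:
                    q += l2
                acc += h2[m] * ring2[a, q]
                q -= 1
            u[a] = acc
            u_m += acc
        if u_m.real == 0.0 and u_m.imag == 0.0:
            theta_w = 0.0
        else:
            theta_w = math.atan2(u_m.imag, u_m.real)
        dth = theta_w - theta_prev
        while dth > math.pi:
            dth -= TWO_PI
        while dth <= -math.pi:
            dth += TWO_PI
        theta_prev = theta_w
        theta_u += dth
        if theta_u > clamp:
            theta_u = clamp
        elif theta_u < -clamp:
            theta_u = -clamp
        e = theta_u / TWO_PI
        deriv = (e - e_prev) * f_bb
        e_prev = e
        integ_new = integ + e / f_bb
        ctrl = kp * e + ki * integ_new + kd * deriv + probe[nn]
        locked = True
        if ctrl >= limit_hz:
            ctrl = limit_hz
            locked = False
        elif ctrl <= -limit_hz:
            ctrl = -limit_hz
            locked = False
        else:
            integ = integ_new
        f_track = omega0_rel + ctrl
        rot = complex(math.cos(theta_w), -math.sin(theta_w))
        for a in range(na):
            r = u[a] * rot
            racc[a] += r
            racc2[a] += r.real * r.real + r.imag * r.imag
        r_m = u_m * rot
        racc[na] += r_m
        racc2[na] += r_m.real * r_m.real + r_m.imag * r_m.imag
        if (nn + 1) % block == 0 and blk < n_blk:
            for a in range(na):
                mr = racc[a] / block
                if mr.real == 0.0 and mr.imag == 0.0:
                    al = 0.0
                else:
                    al = math.atan2(mr.imag, mr.real)
                alpha_blk[a, blk] = al
                dphi[a] += gamma * al
                comp[a] = complex(math.cos(dphi[a]), -math.sin(dphi[a]))
                dphi_blk[a, blk] = dphi[a]
                rmean_blk[a, blk] = mr
                rpow_blk[a, blk] = racc2[a] / block
                racc[a] = complex(0.0, 0.0)
                racc2[a] = 0.0
            rmean_blk[na, blk] = racc[na] / block
            rpow_blk[na, blk] = racc2[na] / block
            racc[na] = complex(0.0, 0.0)
            racc2[na] = 0.0
            blk += 1
        if nn % log_dec == 0:
            j = nn // log_dec
            omega_log[j] = f_track
            theta_log[j] = theta_u
            lock_log[j] = locked
            for a in range(na):
                u_log[a, j] = u[a]
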