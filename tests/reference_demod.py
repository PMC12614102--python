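"""Straight-line pure-Python reference demodulator.

Mirrors the production loop operation by operation (same arithmetic order,
same libm calls) without any compilation, so that the optimized kernel can
be checked for sample-exact agreement on small instances.
"""

import math

import numpy as np

TWO_PI = 2.0 * math.pi


def reference_demodulator(z, rate_hz, h1, h2, d1, d2, omega0_rel, limit_hz,
                          kp, ki, kd, gamma, block, max_turns, log_dec, probe):
    """Return dict of logs equivalent to the production kernel's outputs."""
    na = z.shape[0]
    d = d1 * d2
    n_bb = z.shape[1] // d
    f_bb = rate_hz / d
    l1 = len(h1)
    l2 = len(h2)
    ring1 = [[0j] * l1 for _ in range(na)]
    ring2 = [[0j] * l2 for _ in range(na)]
    u = [0j] * na
    dphi = [0.0] * na
    comp = [complex(1.0, 0.0)] * na
    racc = [0j] * (na + 1)
    racc2 = [0.0] * (na + 1)
    p1 = p2 = idx = 0
    phi = 0.0
    f_track = omega0_rel
    theta_prev = 0.0
    theta_u = 0.0
    e_prev = 0.0
    integ = 0.0
    clamp = TWO_PI * max_turns
    n_blk = n_bb // block
    n_log = (n_bb + log_dec - 1) // log_dec
    out = {
        "omega": np.empty(n_log),
        "theta": np.empty(n_log),
        "lock": np.empty(n_log, dtype=bool),
        "u": np.empty((na, n_log), dtype=complex),
        "alpha": np.empty((na, n_blk)),
        "dphi": np.empty((na, n_blk)),
        "rmean": np.empty((na + 1, n_blk), dtype=complex),
        "rpow": np.empty((na + 1, n_blk)),
    }
    blk = 0
    for nn in range(n_bb):
        for _ in range(d2):
            for _ in range(d1):
                phi += TWO_PI * f_track / rate_hz
                while phi > math.pi:
                    phi -= TWO_PI
                while phi <= -math.pi:
                    phi += TWO_PI
                osc = complex(math.cos(phi), -math.sin(phi))
                for a in range(na):
                    ring1[a][p1] = (z[a, idx] * osc) * comp[a]
                idx += 1
                p1 += 1
                if p1 == l1:
                    p1 = 0
            for a in range(na):
                acc = 0j
                q = p1 - 1
                for m in range(l1):
                    if q < 0:
                        q += l1
                    acc += h1[m] * ring1[a][q]
                    q -= 1
                ring2[a][p2] = acc
            p2 += 1
            if p2 == l2:
                p2 = 0
        u_m = 0j
        for a in range(na):
            acc = 0j
            q = p2 - 1
            for m in range(l2):
                if q < 0:
                    q += l2
                acc += h2[m] * ring2[a][q]
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
                out["alpha"][a, blk] = al
                dphi[a] += gamma * al
                comp[a] = complex(math.cos(dphi[a]), -math.sin(dphi[a]))
                out["dphi"][a, blk] = dphi[a]
                out["rmean"][a, blk] = mr
                out["rpow"][a, blk] = racc2[a] / block
                racc[a] = 0j
                racc2[a] = 0.0
            out["rmean"][na, blk] = racc[na] / block
            out["rpow"][na, blk] = racc2[na] / block
            racc[na] = 0j
            racc2[na] = 0.0
            blk += 1
        if nn % log_dec == 0:
            j = nn // log_dec
            out["omega"][j] = f_track
            out["theta"][j] = theta_u
            out["lock"][j] = locked
            for a in range(na):
                out["u"][a, j] = u[a]
    return out
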