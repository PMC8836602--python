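"""Numba-compiled BAOAB Langevin integrator for the 2D mapping potential.

The kernel integrates the reduced coordinates (r, s) under the FEP mapping
potential (1-lam)*e1 + lam*e2 plus harmonic restraints, recording positions
every ``stride`` steps.  Pre-drawn Gaussian noise keeps the random stream
under the caller's control so runs are bit-reproducible.
"""

import numpy as np
from numba import njit

from .constants import KCAL_TO_INTERNAL


@njit(cache=False)
def baoab_window(
    x,
    v,
    n_steps,
    dt,
    c1,
    c2,
    kbt,
    m_r,
    m_s,
    # state 1: Morse(r), repulsion vs acceptor, harmonic solvent, shifts
    D1,
    b1,
    r01,
    A1,
    k1,
    s1,
    # state 2: Morse(R - r), repulsion vs donor
    D2,
    b2,
    r02,
    A2,
    k2,
    s2,
    R,
    g,
    tc,
    tw,
    lam,
    rk_r,
    rc_r,
    rk_s,
    rc_s,
    noise,
    stride,
    out,
):  # pragma: no cover - exercised via sampler tests
    r = x[0]
    s = x[1]
    vr = v[0]
    vs = v[1]
    F = KCAL_TO_INTERNAL
    sig_r = np.sqrt(kbt * F / m_r)
    sig_s = np.sqrt(kbt * F / m_s)
    n_out = 0

    # gradient of the mapping potential at the current point
    e1 = np.exp(-b1 * (r - r01))
    e2 = np.exp(-b2 * (R - r - r02))
    dr1 = 2.0 * D1 * b1 * (1.0 - e1) * e1 + 12.0 * A1 / (R - r) ** 13
    dr2 = -2.0 * D2 * b2 * (1.0 - e2) * e2 - 12.0 * A2 / r ** 13
    gw = 0.0
    if g != 0.0:
        u = (r - tc) / tw
        gw = g * u / tw * np.exp(-0.5 * u * u)
    fr = -((1.0 - lam) * dr1 + lam * dr2 + gw) - rk_r * (r - rc_r)
    fs = -((1.0 - lam) * k1 * (s - s1) + lam * k2 * (s - s2)) - rk_s * (s - rc_s)

    for step in range(n_steps):
        # B
        vr += 0.5 * dt * fr * F / m_r
        vs += 0.5 * dt * fs * F / m_s
        # A
        r += 0.5 * dt * vr
        s += 0.5 * dt * vs
        # O
        vr = c1 * vr + c2 * sig_r * noise[step, 0]
        vs = c1 * vs + c2 * sig_s * noise[step, 1]
        # A
        r += 0.5 * dt * vr
        s += 0.5 * dt * vs
        # B
        e1 = np.exp(-b1 * (r - r01))
        e2 = np.exp(-b2 * (R - r - r02))
        dr1 = 2.0 * D1 * b1 * (1.0 - e1) * e1 + 12.0 * A1 / (R - r) ** 13
        dr2 = -2.0 * D2 * b2 * (1.0 - e2) * e2 - 12.0 * A2 / r ** 13
        gw = 0.0
        if g != 0.0:
            u = (r - tc) / tw
            gw = g * u / tw * np.exp(-0.5 * u * u)
        fr = -((1.0 - lam) * dr1 + lam * dr2 + gw) - rk_r * (r - rc_r)
        fs = -((1.0 - lam) * k1 * (s - s1) + lam * k2 * (s - s2)) - rk_s * (s - rc_s)
        vr += 0.5 * dt * fr * F / m_r
        vs += 0.5 * dt * fs * F / m_s
        if stride > 0 and (step + 1) % stride == 0:
            out[n_out, 0] = r
            out[n_out, 1] = s
            n_out += 1

    x[0] = r
    x[1] = s
    v[0] = vr
    v[1] = vs
    return n_out
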