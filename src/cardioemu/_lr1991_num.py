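"""Numerical core of the Luo-Rudy 1991 ventricular cell model.

Scalar rate/current formulas plus a fixed-step Rush-Larsen integrator.
All functions are written as plain Python so they work without a JIT, and
are compiled with numba when it is importable (it is in the supported
environment; the fallback keeps the module importable anywhere).

State vector layout (index order used throughout):
    0: V (mV), 1: m, 2: h, 3: j, 4: d, 5: f, 6: X, 7: Cai (mM)
Conductance vector layout:
    0: g_Na, 1: g_si, 2: g_K, 3: g_K1, 4: g_Kp, 5: g_b   (mS/cm^2)
"""

from __future__ import annotations

import math

import numpy as np

try:  # pragma: no cover - exercised implicitly on import
    from numba import njit

    HAVE_NUMBA = True
except ImportError:  # pragma: no cover
    HAVE_NUMBA = False

    def njit(*args, **kwargs):
        if len(args) == 1 and callable(args[0]):
            return args[0]

        def wrap(func):
            return func

        return wrap


# Physical constants (SI-derived, mV/mM/ms unit system)
RTF = 8314.0 * 310.0 / 96484.6  # RT/F in mV
NA_O, NA_I = 140.0, 18.0
K_O, K_I = 5.4, 145.0
PR_NAK = 0.01833

E_NA = RTF * math.log(NA_O / NA_I)
E_K = RTF * math.log((K_O + PR_NAK * NA_O) / (K_I + PR_NAK * NA_I))
E_K1 = RTF * math.log(K_O / K_I)
E_KP = E_K1
E_B = -59.87

# Published initial condition of the model (quiescent cell)
Y0 = np.array(
    [
        -84.3801107371,
        0.00171338077730188,
        0.982660523699656,
        0.989108212766685,
        0.00302126301779861,
        0.999967936476325,
        0.0417603108167287,
        0.00017948816388306,
    ]
)

# Nominal maximum conductances (mS/cm^2) at [K+]o = 5.4 mM
G_NOMINAL = np.array([23.0, 0.09, 0.282, 0.6047, 0.0183, 0.03921])


@njit(cache=True)
def gate_rates(v):
    """Voltage-dependent opening/closing rates of the six HH gates.

    Returns (am, bm, ah, bh, aj, bj, ad, bd, af, bf, ax, bx) in 1/ms.
    """
    dv = v + 47.13
    if abs(dv) < 1e-7:  # removable singularity of alpha_m
        am = 3.2
    else:
        am = 0.32 * dv / (1.0 - math.exp(-0.1 * dv))
    bm = 0.08 * math.exp(-v / 11.0)

    if v < -40.0:
        ah = 0.135 * math.exp((80.0 + v) / -6.8)
        bh = 3.56 * math.exp(0.079 * v) + 310000.0 * math.exp(0.35 * v)
        aj = (
            (-127140.0 * math.exp(0.2444 * v) - 3.474e-5 * math.exp(-0.04391 * v))
            * (v + 37.78)
            / (1.0 + math.exp(0.311 * (v + 79.23)))
        )
        bj = 0.1212 * math.exp(-0.01052 * v) / (1.0 + math.exp(-0.1378 * (v + 40.14)))
    else:
        ah = 0.0
        bh = 1.0 / (0.13 * (1.0 + math.exp((v + 10.66) / -11.1)))
        aj = 0.0
        bj = 0.3 * math.exp(-2.535e-7 * v) / (1.0 + math.exp(-0.1 * (v + 32.0)))

    ad = 0.095 * math.exp(-0.01 * (v - 5.0)) / (1.0 + math.exp(-0.072 * (v - 5.0)))
    bd = 0.07 * math.exp(-0.017 * (v + 44.0)) / (1.0 + math.exp(0.05 * (v + 44.0)))

    af = 0.012 * math.exp(-0.008 * (v + 28.0)) / (1.0 + math.exp(0.15 * (v + 28.0)))
    bf = 0.0065 * math.exp(-0.02 * (v + 30.0)) / (1.0 + math.exp(-0.2 * (v + 30.0)))

    ax = 0.0005 * math.exp(0.083 * (v + 50.0)) / (1.0 + math.exp(0.057 * (v + 50.0)))
    bx = 0.0013 * math.exp(-0.06 * (v + 20.0)) / (1.0 + math.exp(-0.04 * (v + 20.0)))

    return am, bm, ah, bh, aj, bj, ad, bd, af, bf, ax, bx


@njit(cache=True)
def currents(v, m, h, j, d, f, x, cai, g_na, g_si, g_k, g_k1, g_kp, g_b):
    """The six membrane current densities (uA/cm^2) at a given state."""
    i_na = g_na * m * m * m * h * j * (v - E_NA)

    e_si = 7.7 - 13.0287 * math.log(cai)
    i_si = g_si * d * f * (v - e_si)

    if v > -100.0:
        dv77 = v + 77.0
        if abs(dv77) < 1e-7:
            xi = 2.837 * 0.04 / math.exp(0.04 * (v + 35.0))
        else:
            xi = 2.837 * (math.exp(0.04 * dv77) - 1.0) / (dv77 * math.exp(0.04 * (v + 35.0)))
    else:
        xi = 1.0
    i_k = g_k * x * xi * (v - E_K)

    ak1 = 1.02 / (1.0 + math.exp(0.2385 * (v - E_K1 - 59.215)))
    bk1 = (
        0.49124 * math.exp(0.08032 * (v - E_K1 + 5.476))
        + math.exp(0.06175 * (v - E_K1 - 594.31))
    ) / (1.0 + math.exp(-0.5143 * (v - E_K1 + 4.753)))
    i_k1 = g_k1 * (ak1 / (ak1 + bk1)) * (v - E_K1)

    kp = 1.0 / (1.0 + math.exp((7.488 - v) / 5.98))
    i_kp = g_kp * kp * (v - E_KP)

    i_b = g_b * (v - E_B)

    return i_na, i_si, i_k, i_k1, i_kp, i_b


@njit(cache=True)
def derivatives(y, g, i_stim):
    """Right-hand side dy/dt of the model ODE system (per ms)."""
    v, m, h, j, d, f, x, cai = y
    i_na, i_si, i_k, i_k1, i_kp, i_b = currents(
        v, m, h, j, d, f, x, cai, g[0], g[1], g[2], g[3], g[4], g[5]
    )
    am, bm, ah, bh, aj, bj, ad, bd, af, bf, ax, bx = gate_rates(v)
    out = np.empty(8)
    out[0] = -(i_na + i_si + i_k + i_k1 + i_kp + i_b + i_stim)  # C_m = 1 uF/cm^2
    out[1] = am * (1.0 - m) - bm * m
    out[2] = ah * (1.0 - h) - bh * h
    out[3] = aj * (1.0 - j) - bj * j
    out[4] = ad * (1.0 - d) - bd * d
    out[5] = af * (1.0 - f) - bf * f
    out[6] = ax * (1.0 - x) - bx * x
    out[7] = -1e-4 * i_si + 0.07 * (1e-4 - cai)
    return out


@njit(cache=True)
def _rl_step(y, dt, g, i_stim):
    """One Rush-Larsen step: exponential gate update, forward-Euler V and Cai.

    Returns dV/dt at the pre-step state (used to resolve the upstroke
    velocity below the recording-grid resolution).
    """
    v, m, h, j, d, f, x, cai = y
    i_na, i_si, i_k, i_k1, i_kp, i_b = currents(
        v, m, h, j, d, f, x, cai, g[0], g[1], g[2], g[3], g[4], g[5]
    )
    am, bm, ah, bh, aj, bj, ad, bd, af, bf, ax, bx = gate_rates(v)

    dv = -(i_na + i_si + i_k + i_k1 + i_kp + i_b + i_stim)
    y[0] = v + dt * dv
    y[7] = cai + dt * (-1e-4 * i_si + 0.07 * (1e-4 - cai))

    sm = am + bm
    y[1] = am / sm + (m - am / sm) * math.exp(-dt * sm)
    sh = ah + bh
    y[2] = ah / sh + (h - ah / sh) * math.exp(-dt * sh)
    sj = aj + bj
    y[3] = aj / sj + (j - aj / sj) * math.exp(-dt * sj)
    sd = ad + bd
    y[4] = ad / sd + (d - ad / sd) * math.exp(-dt * sd)
    sf = af + bf
    y[5] = af / sf + (f - af / sf) * math.exp(-dt * sf)
    sx = ax + bx
    y[6] = ax / sx + (x - ax / sx) * math.exp(-dt * sx)
    return dv


@njit(cache=True)
def integrate_rl(y0, g, t_end, stim_starts, stim_amp, stim_dur,
                 record_dt, dt_fine, dt_coarse, fine_window):
    """Integrate the model with a two-rate Rush-Larsen scheme.

    A fine step is used inside ``fine_window`` ms after each stimulus onset
    (upstroke), a coarse step elsewhere.  The state is recorded every
    ``record_dt`` ms (which must be an integer multiple of both steps, and
    stimulus onsets must lie on the recording grid).

    Returns (states, dvdt) where states is an (n_rec+1, 8) array of states
    at times k*record_dt and dvdt[k] is the maximum instantaneous dV/dt
    encountered in the interval [k*record_dt, (k+1)*record_dt) (last entry
    repeats the previous interval's value so both arrays align).
    """
    n_rec = int(round(t_end / record_dt))
    out = np.empty((n_rec + 1, 8))
    dvdt = np.empty(n_rec + 1)
    y = y0.copy()
    out[0] = y
    n_fine = int(round(record_dt / dt_fine))
    n_coarse = int(round(record_dt / dt_coarse))
    for k in range(n_rec):
        t0 = k * record_dt
        fine = False
        for s in stim_starts:
            if s <= t0 < s + fine_window:
                fine = True
                break
        if fine:
            nsub, dt = n_fine, dt_fine
        else:
            nsub, dt = n_coarse, dt_coarse
        dvmax = -1e30
        for i in range(nsub):
            t = t0 + i * dt
            i_stim = 0.0
            for s in stim_starts:
                if s - 1e-9 <= t < s + stim_dur - 1e-9:
                    i_stim = stim_amp
                    break
            dv = _rl_step(y, dt, g, i_stim)
            if dv > dvmax:
                dvmax = dv
        out[k + 1] = y
        dvdt[k] = dvmax
    dvdt[n_rec] = dvdt[n_rec - 1] if n_rec > 0 else 0.0
    return out, dvdt
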