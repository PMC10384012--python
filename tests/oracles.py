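"""Independent reference computations used as test oracles.

Everything here is written from the model equations directly, sharing no code
path with the library: trajectories are re-typed inline, the thickness oracle
works by dense sampling + bisection of the radial-ray intersection, and the
coefficient oracles re-evaluate each formula term by term.
"""

from __future__ import annotations

import math

import numpy as np


def traj_xy(ts, j, n_flutes, r, v, omega, r0, psi, Ax, Ay, fx, fy, phix, phiy, phase_extra=0.0):
    """Tip trajectory of tooth j, re-typed from the kinematic equations."""
    ts = np.asarray(ts, dtype=float)
    ang = omega * ts - 2 * math.pi * j / n_flutes - phase_extra
    x = (
        v * ts
        + r * np.sin(ang)
        + r0 * np.sin(omega * ts + psi)
        + Ax * np.sin(2 * math.pi * fx * ts + phix)
    )
    y = (
        r * np.cos(ang)
        + r0 * np.cos(omega * ts + psi)
        + Ay * np.sin(2 * math.pi * fy * ts + phiy)
    )
    return x, y


def center_xy(t, r0, psi, v, omega, Ax, Ay, fx, fy, phix, phiy):
    x = v * t + r0 * math.sin(omega * t + psi) + Ax * math.sin(2 * math.pi * fx * t + phix)
    y = r0 * math.cos(omega * t + psi) + Ay * math.sin(2 * math.pi * fy * t + phiy)
    return x, y


def brute_force_thickness(
    t,
    j,
    *,
    r,
    n_flutes,
    spindle_rpm,
    fz,
    r0=0.0,
    psi=0.0,
    Ax=0.0,
    Ay=0.0,
    fx=0.0,
    fy=0.0,
    phix=0.0,
    phiy=0.0,
    n_samples=100_000,
    theta_d=math.pi,
):
    """Uncut chip thickness by dense sampling of the two prior trajectories.

    Samples each candidate prior trajectory (previous tooth within one tooth
    period, same tooth within one revolution) at ``n_samples`` points, locates
    every crossing of the radial ray from the current tool centre through the
    current tip, refines each by bisection, and returns
    ``h = r - max(L)`` clipped at zero (the outer envelope of prior passes
    governs). Returns 0.0 when the tooth angle is outside the engagement arc.
    """
    omega = 2 * math.pi * spindle_rpm / 60.0
    v = fz * n_flutes * spindle_rpm / 60.0
    kw = dict(
        n_flutes=n_flutes, r=r, v=v, omega=omega, r0=r0, psi=psi,
        Ax=Ax, Ay=Ay, fx=fx, fy=fy, phix=phix, phiy=phiy,
    )
    theta = omega * t - 2 * math.pi * j / n_flutes
    if math.fmod(theta, 2 * math.pi) % (2 * math.pi) > theta_d:
        return 0.0
    ox, oy = center_xy(t, r0, psi, v, omega, Ax, Ay, fx, fy, phix, phiy)
    ux, uy = math.sin(theta), math.cos(theta)

    t_tooth = 60.0 / spindle_rpm / n_flutes
    t_rev = 60.0 / spindle_rpm
    margin = 0.25 * t_tooth
    windows = [
        (j - 1, t - t_tooth - margin, t - 1e-4 * t_tooth),
        (j, t - t_rev - margin, t - t_tooth),
    ]
    best_L = -np.inf
    for jp, lo, hi in windows:
        ts = np.linspace(lo, hi, n_samples)
        xs, ys = traj_xy(ts, jp, **kw)
        cross = (xs - ox) * uy - (ys - oy) * ux
        sign_change = np.flatnonzero(cross[:-1] * cross[1:] <= 0.0)
        for k in sign_change:
            if cross[k] == 0.0 and cross[k + 1] == 0.0:
                continue
            a, b = ts[k], ts[k + 1]
            fa = cross[k]
            for _ in range(80):
                m = 0.5 * (a + b)
                xm, ym = traj_xy(m, jp, **kw)
                fm = (xm - ox) * uy - (ym - oy) * ux
                if fa * fm > 0:
                    a, fa = m, fm
                else:
                    b = m
            ts_root = 0.5 * (a + b)
            xr, yr = traj_xy(ts_root, jp, **kw)
            L = (float(xr) - ox) * ux + (float(yr) - oy) * uy
            if L > 0.0 and L > best_L:
                best_L = L
    if not np.isfinite(best_L):
        return 0.0
    return max(r - best_L, 0.0)


# --- coefficient oracles: term-by-term transcription --------------------------


def armarego_coefficients(tau, mu, gamma_n, lam, with_sqrt=True):
    """Shear coefficients re-evaluated term by term from the oblique model."""
    beta = math.atan(mu)
    phi = math.pi / 4 - (beta - gamma_n) / 2
    eta_c = lam
    denom_sq = math.cos(phi + beta - gamma_n) ** 2 + (math.tan(eta_c) ** 2) * (math.sin(beta) ** 2)
    D = math.sqrt(denom_sq) if with_sqrt else denom_sq
    ktc = (tau / (math.sin(phi) * D)) * (
        math.cos(beta - gamma_n) + math.tan(eta_c) * math.sin(beta) * math.tan(lam)
    )
    krc = (tau / (math.sin(phi) * math.cos(lam) * D)) * math.sin(beta - gamma_n)
    kac = (tau / (math.sin(phi) * D)) * (
        math.cos(beta - gamma_n) * math.tan(lam) - math.tan(eta_c) * math.sin(beta)
    )
    return ktc, krc, kac


def waldorf_ploughing(tau, mu, re, gamma_n, h):
    """Ploughing coefficients re-evaluated step by step from the slip-line model."""
    eta = 0.5 * math.acos(mu)
    l_mn = re * math.sin(eta)
    fp_per_b = tau * math.cos(2 * eta) * l_mn
    if h <= re * (1 + math.sin(gamma_n)):
        gamma_e = math.acos((re - h) / re) - math.pi / 2
    else:
        gamma_e = gamma_n
    ktp = fp_per_b * abs(math.sin(gamma_e))
    krp = fp_per_b * math.cos(gamma_e)
    return ktp, krp
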