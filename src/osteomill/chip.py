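"""Instantaneous uncut chip thickness under vibratory, runout-perturbed kinematics.

With platform vibration the surface a tooth meets is no longer the smooth
trochoid of the preceding tooth: trajectories of successive passes interlock,
and a tooth may momentarily separate from the material (an *empty cut*). Four
cases are distinguished, depending on whether the current tip lies outside the
contour already machined, and on which earlier pass formed that contour:

* chip / empty cut against the **previous tooth's** trajectory,
* chip / empty cut against the **same tooth's** previous revolution.

The thickness is resolved along the tool radius: find the time ``t_s < t`` at
which an earlier tip trajectory crosses the ray from the current tool centre
``O(t)`` through the current tip ``P(t)`` (a collinearity condition), measure
``L_OPs = |P_s - O|``, and take ``h = r - L_OPs``. Both candidate prior
trajectories are solved; material survives only outside the *outer envelope*
of all earlier passes, so the governing surface is the intersection farthest
from the centre (equivalently the smallest nonnegative candidate thickness,
or an empty cut if every candidate lies beyond the tip radius).

Vibration makes the collinearity residual oscillatory, so each search window
is scanned on a uniform grid for sign changes and every bracket is refined by
bisection — a single-start Newton/fsolve iteration can land on the wrong
branch. Trajectories are evaluated at negative times as well, which gives the
first revolution a well-defined virtual prior surface; steady-state outputs
discard revolution 1 regardless.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd
from scipy.optimize import brentq

from .kinematics import ProcessParams, VibrationParams, center_position, tip_position, time_grid
from .tooling import CutterGeometry

__all__ = [
    "ChipSample",
    "ThicknessProfile",
    "collinearity_residual",
    "solve_previous_time",
    "chip_thickness_at",
    "thickness_profile",
    "removed_area_per_revolution",
    "CASE_TAGS",
]

# case codes
NOT_ENGAGED = 0
CHIP_PREV = 1
EMPTY_PREV = 2
CHIP_SAME = 3
EMPTY_SAME = 4

CASE_TAGS = {
    NOT_ENGAGED: "not-engaged",
    CHIP_PREV: "chip-different-tooth",
    EMPTY_PREV: "empty-different-tooth",
    CHIP_SAME: "chip-same-tooth",
    EMPTY_SAME: "empty-same-tooth",
}

#: scan points per search window when bracketing collinearity roots
N_SCAN = 200
#: bisection iterations (window width ~ms -> root localised far below 1e-12 s)
N_BISECT = 60
#: window margin, as a fraction of the tooth period
WINDOW_MARGIN = 0.25


@dataclass(frozen=True)
class ChipSample:
    """Resolved thickness of one tooth at one instant."""

    t: float
    j: int
    theta: float  # unwrapped tooth-position angle (rad)
    h: float  # uncut chip thickness (m), >= 0
    case_tag: str
    t_s: Optional[float] = None  # matched earlier time on the governing trajectory


class _Consts:
    """Scalar trajectory constants unpacked once per resolve call."""

    __slots__ = ("r", "v", "omega", "r0", "psi", "Ax", "Ay", "wx", "wy", "phix", "phiy")

    def __init__(self, geom: CutterGeometry, vib: VibrationParams, proc: ProcessParams):
        self.r = geom.radius
        self.v = proc.feed_speed
        self.omega = proc.omega
        self.r0 = geom.runout
        self.psi = geom.runout_angle
        self.Ax, self.Ay = vib.Ax, vib.Ay
        self.wx, self.wy = 2 * math.pi * vib.fx, 2 * math.pi * vib.fy
        self.phix, self.phiy = vib.phix, vib.phiy


def _traj(ts, phase, c: _Consts):
    """Tip trajectory with tooth-phase ``phase`` (x, y); vectorized over ts."""
    ang = c.omega * ts - phase
    x = c.v * ts + c.r * np.sin(ang)
    y = c.r * np.cos(ang)
    if c.r0 != 0.0:
        run = c.omega * ts + c.psi
        x = x + c.r0 * np.sin(run)
        y = y + c.r0 * np.cos(run)
    if c.Ax != 0.0:
        x = x + c.Ax * np.sin(c.wx * ts + c.phix)
    if c.Ay != 0.0:
        y = y + c.Ay * np.sin(c.wy * ts + c.phiy)
    return x, y


def _cross_residual(ts, phase_prev, ox, oy, ux, uy, c: _Consts):
    """Signed (dimensionless) offset of the prior trajectory from the tip ray."""
    xs, ys = _traj(ts, phase_prev, c)
    return ((xs - ox) * uy - (ys - oy) * ux) / c.r


def _resolve(
    tq: np.ndarray,
    j: int,
    geom: CutterGeometry,
    vib: VibrationParams,
    proc: ProcessParams,
    *,
    phase_offset: float = 0.0,
    theta_d: float = math.pi,
    n_scan: int = N_SCAN,
):
    """Resolve thickness for an array of query times of tooth ``j``.

    Returns (theta_unwrapped, h, case_code, t_match) arrays. ``phase_offset``
    shifts the tooth phase (used for axial flute slices that lag the tip).
    """
    c = _Consts(geom, vib, proc)
    tq = np.asarray(tq, dtype=float)
    phase_j = 2 * math.pi * j / proc.n_flutes + phase_offset
    theta = c.omega * tq - phase_j

    h = np.zeros_like(tq)
    case = np.zeros(tq.shape, dtype=np.int8)
    t_match = np.full_like(tq, np.nan)

    engaged = (np.mod(theta, 2 * math.pi) <= theta_d)
    if not engaged.any():
        return theta, h, case, t_match

    idx = np.flatnonzero(engaged)
    te = tq[idx]
    ang = theta[idx]
    ux, uy = np.sin(ang), np.cos(ang)
    run = c.omega * te + c.psi
    ox = c.v * te + (c.r0 * np.sin(run) if c.r0 else 0.0) + (
        c.Ax * np.sin(c.wx * te + c.phix) if c.Ax else 0.0
    )
    oy = (c.r0 * np.cos(run) if c.r0 else 0.0) + (
        c.Ay * np.sin(c.wy * te + c.phiy) if c.Ay else 0.0
    )
    ox = np.broadcast_to(np.asarray(ox, float), te.shape).copy()
    oy = np.broadcast_to(np.asarray(oy, float), te.shape).copy()

    t_tooth = proc.tooth_period
    t_rev = proc.rev_period
    margin = WINDOW_MARGIN * t_tooth
    # (phase of the prior trajectory, window lower offset, window upper offset)
    windows = [
        (phase_j - 2 * math.pi / proc.n_flutes, -t_tooth - margin, -1e-4 * t_tooth, CHIP_PREV, EMPTY_PREV),
    ]
    if proc.n_flutes > 1:
        windows.append((phase_j, -t_rev - margin, -t_tooth, CHIP_SAME, EMPTY_SAME))
    else:
        windows = [(phase_j, -t_rev - margin, -1e-4 * t_rev, CHIP_SAME, EMPTY_SAME)]

    best_L = np.full(te.shape, -np.inf)
    best_ts = np.full(te.shape, np.nan)
    best_w = np.full(te.shape, -1, dtype=np.int8)

    for w_id, (phase_prev, lo_off, hi_off, _, _) in enumerate(windows):
        # chunk rows to bound memory: rows x n_scan doubles
        for start in range(0, te.size, 4096):
            sl = slice(start, min(start + 4096, te.size))
            tr = te[sl]
            offs = np.linspace(lo_off, hi_off, n_scan)
            ts_grid = tr[:, None] + offs[None, :]
            R = _cross_residual(
                ts_grid, phase_prev, ox[sl][:, None], oy[sl][:, None], ux[sl][:, None], uy[sl][:, None], c
            )
            prod = R[:, :-1] * R[:, 1:]
            brk = prod <= 0.0
            brk &= ~((R[:, :-1] == 0.0) & (R[:, 1:] == 0.0))
            rows, cols = np.nonzero(brk)
            if rows.size == 0:
                continue
            lo = ts_grid[rows, cols]
            hi = ts_grid[rows, cols + 1]
            R_lo = R[rows, cols]
            r_ox, r_oy = ox[sl][rows], oy[sl][rows]
            r_ux, r_uy = ux[sl][rows], uy[sl][rows]
            for _ in range(N_BISECT):
                mid = 0.5 * (lo + hi)
                Rm = _cross_residual(mid, phase_prev, r_ox, r_oy, r_ux, r_uy, c)
                same = R_lo * Rm > 0.0
                lo = np.where(same, mid, lo)
                R_lo = np.where(same, Rm, R_lo)
                hi = np.where(same, hi, mid)
            ts_root = 0.5 * (lo + hi)
            xs, ys = _traj(ts_root, phase_prev, c)
            L = (xs - r_ox) * r_ux + (ys - r_oy) * r_uy  # signed ray parameter
            valid = L > 0.0
            if not valid.any():
                continue
            # per-row maximum L among this window's valid roots: sort by
            # (row, L) with invalid roots pushed to -inf; each run's last
            # element is that row's governing intersection
            g_rows = rows + start
            L_eff = np.where(valid, L, -np.inf)
            order = np.lexsort((L_eff, g_rows))
            g_sorted = g_rows[order]
            L_sorted = L_eff[order]
            ts_sorted = ts_root[order]
            run_end = np.flatnonzero(np.r_[g_sorted[1:] != g_sorted[:-1], True])
            row_ids = g_sorted[run_end]
            L_max = L_sorted[run_end]
            ts_at_max = ts_sorted[run_end]
            better = L_max > best_L[row_ids]
            upd = row_ids[better]
            best_L[upd] = L_max[better]
            best_ts[upd] = ts_at_max[better]
            best_w[upd] = w_id

    found = np.isfinite(best_L) & (best_L > -np.inf) & (best_w >= 0)
    h_cand = np.where(found, c.r - best_L, 0.0)
    chip = found & (h_cand > 0.0)
    empty = found & ~chip
    case_e = np.zeros(te.shape, dtype=np.int8)
    prev_w = best_w == 0 if proc.n_flutes > 1 else np.zeros(te.shape, bool)
    case_e[chip & prev_w] = CHIP_PREV
    case_e[chip & ~prev_w] = CHIP_SAME
    case_e[empty & prev_w] = EMPTY_PREV
    case_e[empty & ~prev_w] = EMPTY_SAME

    h[idx] = np.where(chip, h_cand, 0.0)
    case[idx] = case_e
    t_match[idx] = np.where(found, best_ts, np.nan)
    return theta, h, case, t_match


def collinearity_residual(
    t: float,
    t_s: float,
    j: int,
    j_prev: int,
    geom: CutterGeometry,
    vib: VibrationParams,
    proc: ProcessParams,
) -> float:
    """Collinearity of tool centre O(t), current tip P(t) and prior point P_s(t_s).

    Cross-product form ``(xo - x)(y - ys) - (yo - y)(x - xs)``, normalised by
    r^2; zero exactly when P_s(t_s) on trajectory ``j_prev`` lies on the line
    through the tool centre and the tip of tooth ``j``.
    """
    x, y = tip_position(t, j, geom, vib, proc)
    xo, yo = center_position(t, geom, vib, proc)
    xs, ys = tip_position(t_s, j_prev, geom, vib, proc)
    return float(((xo - x) * (y - ys) - (yo - y) * (x - xs)) / geom.radius**2)


def solve_previous_time(
    t: float,
    j: int,
    which: str,
    geom: CutterGeometry,
    vib: VibrationParams,
    proc: ProcessParams,
    *,
    n_scan: int = N_SCAN,
) -> Optional[float]:
    """Earlier time ``t_s`` at which the chosen prior trajectory meets the tip ray.

    ``which`` is ``"previous-tooth"`` (the preceding flute's pass, searched
    within roughly one tooth period back) or ``"same-tooth"`` (this flute's
    previous revolution). Among the roots with a nonnegative resulting
    thickness the one giving the smallest thickness (the governing surface) is
    returned; ``None`` if no admissible root exists in the window, which
    downstream becomes an empty cut.
    """
    c = _Consts(geom, vib, proc)
    phase_j = 2 * math.pi * j / proc.n_flutes
    if which == "previous-tooth":
        phase_prev = phase_j - 2 * math.pi / proc.n_flutes
        lo = t - proc.tooth_period - WINDOW_MARGIN * proc.tooth_period
        hi = t - 1e-4 * proc.tooth_period
    elif which == "same-tooth":
        phase_prev = phase_j
        lo = t - proc.rev_period - WINDOW_MARGIN * proc.tooth_period
        hi = t - proc.tooth_period
    else:
        raise ValueError(f"which must be 'previous-tooth' or 'same-tooth', got {which!r}")

    ang = c.omega * t - phase_j
    ux, uy = math.sin(ang), math.cos(ang)
    oxa, oya = center_position(t, geom, vib, proc)
    ox, oy = float(oxa), float(oya)

    def f(ts):
        return float(_cross_residual(np.asarray(ts, float), phase_prev, ox, oy, ux, uy, c))

    grid = np.linspace(lo, hi, n_scan)
    vals = np.array([f(g) for g in grid])
    best = None  # (h, ts)
    for k in np.flatnonzero(vals[:-1] * vals[1:] <= 0.0):
        if vals[k] == 0.0 and vals[k + 1] == 0.0:
            continue
        try:
            ts_root = brentq(f, grid[k], grid[k + 1], xtol=1e-13, rtol=8.9e-16)
        except ValueError as exc:  # pragma: no cover - bracket guaranteed by sign change
            raise RuntimeError(
                f"collinearity root refinement failed (t={t}, j={j}, window=({grid[k]}, {grid[k+1]}))"
            ) from exc
        xs, ys = _traj(np.asarray(ts_root), phase_prev, c)
        L = (float(xs) - ox) * ux + (float(ys) - oy) * uy
        if L <= 0.0:
            continue
        h = geom.radius - L
        if h >= 0.0 and (best is None or h < best[0]):
            best = (h, ts_root)
    return None if best is None else best[1]


def chip_thickness_at(
    t: float,
    j: int,
    geom: CutterGeometry,
    vib: VibrationParams,
    proc: ProcessParams,
    *,
    theta_d: float = math.pi,
) -> ChipSample:
    """Resolve the uncut chip thickness of tooth ``j`` at time ``t``."""
    theta, h, case, t_match = _resolve(np.array([t]), j, geom, vib, proc, theta_d=theta_d)
    ts = float(t_match[0])
    return ChipSample(
        t=float(t),
        j=j,
        theta=float(theta[0]),
        h=float(h[0]),
        case_tag=CASE_TAGS[int(case[0])],
        t_s=None if math.isnan(ts) else ts,
    )


@dataclass(frozen=True)
class ThicknessProfile:
    """Dense per-tooth thickness arrays on a uniform time grid.

    ``theta``, ``h``, ``case`` and ``t_match`` are (n_flutes, n_times) arrays;
    ``theta`` is the unwrapped tooth-position angle of each flute's tip.
    """

    t: np.ndarray
    dt: float
    theta: np.ndarray
    h: np.ndarray
    case: np.ndarray
    t_match: np.ndarray
    geom: CutterGeometry
    vib: VibrationParams
    proc: ProcessParams

    @property
    def n_flutes(self) -> int:
        return self.h.shape[0]

    @property
    def steps_per_revolution(self) -> int:
        return int(round(self.proc.rev_period / self.dt))

    def to_dataframe(self) -> pd.DataFrame:
        """Long-format export: t_s, tooth, theta_deg, h_um, case_tag."""
        frames = []
        for j in range(self.n_flutes):
            frames.append(
                pd.DataFrame(
                    {
                        "t_s": self.t,
                        "tooth": j,
                        "theta_deg": np.degrees(self.theta[j]),
                        "h_um": self.h[j] * 1e6,
                        "case_tag": [CASE_TAGS[int(k)] for k in self.case[j]],
                    }
                )
            )
        return pd.concat(frames, ignore_index=True)


def thickness_profile(
    geom: CutterGeometry,
    vib: VibrationParams,
    proc: ProcessParams,
    n_revolutions: int,
    dt: Optional[float] = None,
    *,
    samples_per_cycle: int = 50,
    theta_d: float = math.pi,
) -> ThicknessProfile:
    """Thickness of every flute over ``n_revolutions`` spindle revolutions.

    The grid resolves the fastest vibration/tooth-passing frequency (see
    :func:`osteomill.kinematics.time_grid`) unless an explicit ``dt`` is given.
    Revolution 1 is kept in the arrays (force assembly needs the lead-in) —
    steady-state consumers slice it off.
    """
    if n_revolutions < 2:
        raise ValueError("need at least 2 revolutions (revolution 1 is start-up transient)")
    if dt is None:
        t, dt = time_grid(vib, proc, n_revolutions, samples_per_cycle)
    else:
        n = int(round(n_revolutions * proc.rev_period / dt))
        t = np.arange(n) * dt
    n_fl = proc.n_flutes
    theta = np.empty((n_fl, t.size))
    h = np.empty((n_fl, t.size))
    case = np.empty((n_fl, t.size), dtype=np.int8)
    t_match = np.empty((n_fl, t.size))
    for j in range(n_fl):
        theta[j], h[j], case[j], t_match[j] = _resolve(t, j, geom, vib, proc, theta_d=theta_d)
    return ThicknessProfile(
        t=t, dt=dt, theta=theta, h=h, case=case, t_match=t_match, geom=geom, vib=vib, proc=proc
    )


def removed_area_per_revolution(profile: ThicknessProfile, discard: int = 1) -> np.ndarray:
    """Cross-section area removed per revolution: sum_j int h r dtheta.

    In steady state this must equal the feed per revolution times the slot
    width, ``N fz * 2 r`` — vibration redistributes the removed material over
    the engagement arc but cannot create or destroy it. The first ``discard``
    revolutions are dropped as start-up transient.
    """
    spr = profile.steps_per_revolution
    n_rev = profile.t.size // spr
    dtheta = profile.proc.omega * profile.dt
    areas = []
    for k in range(discard, n_rev):
        sl = slice(k * spr, (k + 1) * spr)
        areas.append(float(np.sum(profile.h[:, sl]) * profile.geom.radius * dtheta))
    return np.asarray(areas)
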