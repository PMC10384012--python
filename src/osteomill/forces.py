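"""Micro-element force integration along engaged flute segments.

Each flute is discretized into axial slices of height ``dz``. A slice at
height ``z`` lags the flute bottom by the helix lag ``theta_z(z)``; its chip
thickness is the tooth's thickness profile evaluated at the lagged tooth
angle. Per slice and per direction ``i`` the oblique-cutting micro-element
forces are

    dFt = Ktc_i h dz + Ktp_i dz      (tangential: shear + ploughing)
    dFr = Krc_i h dz + Krp_i dz      (radial:     shear + ploughing)
    dFa = Kac_i h dz                 (axial:      shear only)

with no ploughing contribution while the edge is separated from the material
(h = 0): vibration-induced separation removes the rubbing contact entirely.
The axial ploughing coefficient has no closed form in this model and defaults
to zero (``kap`` hook provided). Engaged slices rotate into the workpiece
frame as

    dFx = + dFt cos(theta) + dFr sin(theta)
    dFy = - dFt sin(theta) + dFr cos(theta)
    dFz = - dFa
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Any, Dict, Optional

import numpy as np
import pandas as pd

from .coefficients import ploughing_coefficients, shear_coefficients
from .kinematics import ProcessParams, VibrationParams
from .materials import BoneMaterial
from .tooling import CutterGeometry
from .chip import ThicknessProfile, thickness_profile

__all__ = ["ForceTrace", "elemental_forces", "assemble_forces", "simulate"]


@dataclass(frozen=True)
class ForceTrace:
    """Workpiece-frame force time series with its generating configuration."""

    t: np.ndarray
    theta: np.ndarray  # tooth-0 bottom angle, degrees, unwrapped
    Fx: np.ndarray
    Fy: np.ndarray
    Fz: np.ndarray
    params: Dict[str, Any] = field(default_factory=dict)

    def __post_init__(self) -> None:
        n = self.t.size
        if not (self.theta.size == self.Fx.size == self.Fy.size == self.Fz.size == n):
            raise ValueError("force trace arrays must share one length")

    @property
    def dt(self) -> float:
        return float(self.t[1] - self.t[0]) if self.t.size > 1 else math.nan

    @property
    def sample_rate(self) -> float:
        return 1.0 / self.dt

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "t_s": self.t,
                "theta_deg": self.theta,
                "Fx_N": self.Fx,
                "Fy_N": self.Fy,
                "Fz_N": self.Fz,
            }
        )

    def replace_forces(self, Fx, Fy, Fz, **extra_params) -> "ForceTrace":
        params = dict(self.params)
        params.update(extra_params)
        return ForceTrace(t=self.t, theta=self.theta, Fx=Fx, Fy=Fy, Fz=Fz, params=params)


def elemental_forces(h: float, dz: float, coeffs) -> tuple:
    """Tangential/radial/axial force of one micro-element (vectorized over h).

    Zero thickness transmits no force at all — shear scales with h and
    ploughing requires edge–material contact.
    """
    h = np.asarray(h, dtype=float)
    if np.any(h < 0):
        raise ValueError("chip thickness must be nonnegative")
    if not dz > 0:
        raise ValueError("slice height dz must be positive")
    contact = h > 0
    dft = np.where(contact, coeffs.Ktc * h * dz + coeffs.Ktp * dz, 0.0)
    dfr = np.where(contact, coeffs.Krc * h * dz + coeffs.Krp * dz, 0.0)
    dfa = np.where(contact, coeffs.Kac * h * dz, 0.0)
    if h.ndim == 0:
        return float(dft), float(dfr), float(dfa)
    return dft, dfr, dfa


def assemble_forces(
    profile: ThicknessProfile,
    geom: CutterGeometry,
    proc: ProcessParams,
    mat: BoneMaterial,
    *,
    n_slices: int = 20,
    theta_d: float = math.pi,
    armarego_sqrt: bool = True,
    slipline_length: str = "product",
    ploughing: bool = True,
    kap: float = 0.0,
    flip_y: bool = False,
) -> ForceTrace:
    """Integrate slice forces over flutes and axial depth into Fx/Fy/Fz(t).

    The flute over the axial depth H is split into ``n_slices`` slices of
    height ``dz = H / n_slices`` centred at ``z_k``; slice k of tooth j cuts
    at the lagged angle ``theta_j(t) - theta_z(z_k)`` with the thickness the
    tip profile shows at that angle (a time shift of ``theta_z / omega``).
    ``flip_y`` mirrors the Y force for comparison against dynamometers whose
    Y axis opposes the model frame.
    """
    if profile.proc.n_flutes != proc.n_flutes:
        raise ValueError("profile and process disagree on flute count")
    if not np.isclose(profile.proc.omega, proc.omega):
        raise ValueError("profile and process disagree on spindle speed")
    t = profile.t
    omega = proc.omega
    H = proc.axial_depth
    dz = H / n_slices
    z_k = (np.arange(n_slices) + 0.5) * dz
    lag_k = np.tan(geom.helix_angle) * z_k / geom.radius

    direction = proc.direction
    ktc, krc, kac = shear_coefficients(mat, geom, direction, armarego_sqrt=armarego_sqrt)

    fx = np.zeros_like(t)
    fy = np.zeros_like(t)
    fz = np.zeros_like(t)
    two_pi = 2 * math.pi
    for j in range(proc.n_flutes):
        theta_j = profile.theta[j]
        for lag in lag_k:
            t_lag = t - lag / omega
            h = np.interp(t_lag, t, profile.h[j], left=0.0)
            ang = theta_j - lag
            engaged = (np.mod(ang, two_pi) <= theta_d) & (h > 0.0)
            if not engaged.any():
                continue
            he = h[engaged]
            if ploughing:
                ktp, krp = ploughing_coefficients(
                    mat, geom, direction, he, slipline_length=slipline_length
                )
            else:
                ktp = krp = 0.0
            dft = ktc * he * dz + ktp * dz
            dfr = krc * he * dz + krp * dz
            dfa = kac * he * dz + kap * dz
            a = ang[engaged]
            ca, sa = np.cos(a), np.sin(a)
            fx[engaged] += dft * ca + dfr * sa
            fy[engaged] += -dft * sa + dfr * ca
            fz[engaged] += -dfa
    if flip_y:
        fy = -fy
    params = {
        "n_slices": n_slices,
        "theta_d": theta_d,
        "armarego_sqrt": armarego_sqrt,
        "slipline_length": slipline_length,
        "ploughing": ploughing,
        "kap": kap,
        "flip_y": flip_y,
        "direction": int(direction),
        "spindle_speed_rpm": proc.spindle_speed,
        "feed_per_tooth_m": proc.feed_per_tooth,
        "axial_depth_m": proc.axial_depth,
        "n_flutes": proc.n_flutes,
        "radius_m": geom.radius,
        "helix_angle_rad": geom.helix_angle,
        "rake_angle_rad": geom.rake_angle,
        "edge_radius_m": geom.edge_radius,
        "runout_m": geom.runout,
        "runout_angle_rad": geom.runout_angle,
        "Ax_m": profile.vib.Ax,
        "Ay_m": profile.vib.Ay,
        "fx_Hz": profile.vib.fx,
        "fy_Hz": profile.vib.fy,
        "phix_rad": profile.vib.phix,
        "phiy_rad": profile.vib.phiy,
        "dt_s": profile.dt,
    }
    return ForceTrace(t=t, theta=np.degrees(profile.theta[0]), Fx=fx, Fy=fy, Fz=fz, params=params)


def simulate(
    mat: BoneMaterial,
    geom: CutterGeometry,
    vib: VibrationParams,
    proc: ProcessParams,
    n_revolutions: int = 4,
    dt: Optional[float] = None,
    *,
    discard_revolutions: int = 1,
    profile: Optional[ThicknessProfile] = None,
    **assemble_opts,
) -> ForceTrace:
    """Full pipeline: kinematics -> chip thickness -> force assembly.

    Deterministic (no randomness anywhere): identical configurations yield
    bit-identical traces. The first ``discard_revolutions`` revolutions are
    dropped as start-up transient; the returned trace covers whole
    revolutions, as RMS windows require. A precomputed thickness ``profile``
    may be passed to amortise the implicit solve across material directions
    (thickness is purely kinematic).
    """
    if profile is None:
        profile = thickness_profile(geom, vib, proc, n_revolutions, dt)
    trace = assemble_forces(profile, geom, proc, mat, **assemble_opts)
    spr = profile.steps_per_revolution
    sl = slice(discard_revolutions * spr, None)
    params = dict(trace.params)
    params["n_revolutions"] = n_revolutions
    params["discard_revolutions"] = discard_revolutions
    return ForceTrace(
        t=trace.t[sl], theta=trace.theta[sl], Fx=trace.Fx[sl], Fy=trace.Fy[sl], Fz=trace.Fz[sl],
        params=params,
    )
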