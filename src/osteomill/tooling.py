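"""Cutter geometry and helical-flute engagement bookkeeping.

A flat-end micro-mill is modelled as a stack of oblique-cutting micro-elements
along the axis. Because of the helix, the element at axial height ``z`` lags
the bottom of the flute by ``theta_z = tan(lambda) * z / r``; the engaged part
of a flute at bottom angle ``theta`` therefore spans an angular window whose
limits depend on the cutting zone (entry / continuous / exit).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional

__all__ = ["CutterGeometry", "EngagementLimits", "lag_angle", "engagement_limits", "default_cutter"]


@dataclass(frozen=True)
class CutterGeometry:
    """Geometry of a helical flat-end micro-mill (SI units).

    Attributes
    ----------
    radius
        Tool radius r (m).
    rake_angle
        Nominal rake angle gamma_n (rad).
    clearance_angle
        Clearance (back) angle alpha_n (rad); carried for completeness, it
        does not enter the force formulas.
    helix_angle
        Helix angle lambda (rad); taken equal to the edge inclination angle
        of the oblique-cutting elements.
    edge_radius
        Blunt-circle (cutting edge) radius re (m); sets the ploughing scale
        and the equivalent rake angle at small chip thickness.
    runout
        Radial runout (eccentricity) r0 of the cutter axis (m).
    runout_angle
        Phase psi of the runout direction relative to tooth 0 (rad).
    n_flutes
        Number of cutting edges N.
    """

    radius: float
    rake_angle: float
    clearance_angle: float
    helix_angle: float
    edge_radius: float
    runout: float = 0.0
    runout_angle: float = 0.0
    n_flutes: int = 2

    def __post_init__(self) -> None:
        if not self.radius > 0:
            raise ValueError("radius must be positive")
        if not 0 < self.edge_radius < self.radius:
            raise ValueError("edge_radius must satisfy 0 < re < r")
        if self.runout < 0:
            raise ValueError("runout must be nonnegative")
        if self.n_flutes < 1:
            raise ValueError("n_flutes must be >= 1")
        if not 0 < self.helix_angle < math.pi / 2:
            raise ValueError("helix_angle must lie in (0, pi/2)")


@dataclass(frozen=True)
class EngagementLimits:
    """Angular integration window [theta_st, theta_ex] of an engaged flute."""

    theta_st: float
    theta_ex: float

    def __post_init__(self) -> None:
        if not self.theta_st <= self.theta_ex:
            raise ValueError("theta_st must not exceed theta_ex")


def lag_angle(geom: CutterGeometry, z: float) -> float:
    """Helix lag theta_z = tan(lambda) * z / r at axial height z >= 0."""
    if z < 0:
        raise ValueError(f"axial height must be nonnegative, got {z}")
    return math.tan(geom.helix_angle) * z / geom.radius


def engagement_limits(
    theta: float, theta_z: float, theta_d: float = math.pi
) -> Optional[EngagementLimits]:
    """Integration limits of a helical flute at bottom tooth angle ``theta``.

    ``theta_z`` is the total helix lag over the axial depth of cut and
    ``theta_d`` the maximum engagement angle (pi for two-flute slot milling).
    Three zones:

    * entry, ``0 <= theta <= theta_z``: (0, theta) — the flute is winding in;
    * continuous, ``theta_z < theta <= theta_d``: (theta - theta_z, theta);
    * exit, ``theta_d < theta <= theta_d + theta_z``: (theta - theta_z, theta_d).

    Outside these the flute is not engaged and ``None`` is returned.
    """
    if theta_z < 0:
        raise ValueError("theta_z must be nonnegative")
    if 0 <= theta <= theta_z:
        return EngagementLimits(0.0, theta)
    if theta_z < theta <= theta_d:
        return EngagementLimits(theta - theta_z, theta)
    if theta_d < theta <= theta_d + theta_z:
        return EngagementLimits(theta - theta_z, theta_d)
    return None


def default_cutter() -> CutterGeometry:
    """Two-flute coated tungsten-carbide micro-mill, 0.8 mm diameter.

    r = 400 um, rake 5 deg, clearance 10 deg, helix 35 deg, edge radius 5 um,
    runout 2 um (runout phase defaults to 0 — it is not reported), N = 2.
    """
    return CutterGeometry(
        radius=400e-6,
        rake_angle=math.radians(5.0),
        clearance_angle=math.radians(10.0),
        helix_angle=math.radians(35.0),
        edge_radius=5e-6,
        runout=2e-6,
        runout_angle=0.0,
        n_flutes=2,
    )
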