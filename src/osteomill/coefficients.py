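"""Shear and ploughing force coefficients for oblique micro-cutting of bone.

Shear coefficients follow Armarego's oblique (bevel) cutting theory: the
helical flute is treated as an inclined cutting edge with edge inclination
equal to the helix angle, the chip flows along the edge at the chip-flow angle
``eta_c = lambda``, and the normal shear angle comes from a Merchant-type
relation ``phi = pi/4 - (beta - gamma_n)/2``.

Ploughing (edge-rubbing) forces follow a Waldorf-style slip-line field under
the blunt edge: the slip-line angle is ``eta = 0.5*arccos(mu)``, the ploughed
contact length is ``l_MN = re*sin(eta)``, and the ploughing force per unit
edge width is ``F_p/b = tau * cos(2 eta) * l_MN``. At chip thickness
comparable to the edge radius, the edge presents a strongly negative
*equivalent rake angle* which splits the ploughing force into tangential and
radial components.

Coefficients are stored as nonnegative magnitudes; the sign/sense of each
component is applied once in the force decomposition
(:func:`osteomill.forces.assemble_forces`).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Tuple, Union

import numpy as np

from .materials import BoneMaterial, Direction, friction_angle, slip_line_angle
from .tooling import CutterGeometry

__all__ = [
    "ShearGeometry",
    "CoefficientSet",
    "shear_angle",
    "shear_coefficients",
    "equivalent_rake_angle",
    "ploughing_coefficients",
    "coefficient_set",
]


@dataclass(frozen=True)
class ShearGeometry:
    """Angles of the oblique shear model (all rad)."""

    shear_angle: float
    friction_angle: float
    chip_flow_angle: float


@dataclass(frozen=True)
class CoefficientSet:
    """Cutting coefficients: shear (Pa, per chip area) and ploughing (N/m of edge)."""

    Ktc: float
    Krc: float
    Kac: float
    Ktp: float
    Krp: float


def shear_angle(beta: float, gamma_n: float) -> float:
    """Normal shear angle phi = pi/4 - (beta - gamma_n)/2, required in (0, pi/2)."""
    phi = math.pi / 4 - (beta - gamma_n) / 2
    if not 0 < phi < math.pi / 2:
        raise ValueError(
            f"shear angle {phi} rad outside (0, pi/2); check friction/rake configuration"
        )
    return phi


def shear_geometry(mat: BoneMaterial, geom: CutterGeometry, direction) -> ShearGeometry:
    """Bundle the shear/friction/chip-flow angles for one cutting direction."""
    beta = friction_angle(mat.friction(direction))
    phi = shear_angle(beta, geom.rake_angle)
    return ShearGeometry(shear_angle=phi, friction_angle=beta, chip_flow_angle=geom.helix_angle)


def shear_coefficients(
    mat: BoneMaterial,
    geom: CutterGeometry,
    direction: Union[Direction, int, str],
    *,
    armarego_sqrt: bool = True,
) -> Tuple[float, float, float]:
    """Oblique-cutting shear coefficients (Ktc, Krc, Kac) in Pa.

    With tau the directional shear strength, beta the friction angle, phi the
    shear angle, gamma_n the rake and eta_c = lambda the chip-flow angle:

        D   = sqrt(cos^2(phi+beta-gamma_n) + tan^2(eta_c) sin^2(beta))
        Ktc = tau [cos(beta-gamma_n) + tan(eta_c) tan(lambda) sin(beta)] / (sin(phi) D)
        Krc = tau sin(beta-gamma_n) / (sin(phi) cos(lambda) D)
        Kac = tau [cos(beta-gamma_n) tan(lambda) - tan(eta_c) sin(beta)] / (sin(phi) D)

    ``armarego_sqrt=False`` drops the radical on D (a literal reading of the
    compact typeset form of the model); the default keeps it, matching
    Armarego's published oblique model.
    """
    direction = Direction.coerce(direction)
    tau = mat.shear_strength(direction)
    sg = shear_geometry(mat, geom, direction)
    beta, phi = sg.friction_angle, sg.shear_angle
    gamma_n, lam = geom.rake_angle, geom.helix_angle
    eta_c = sg.chip_flow_angle

    d2 = math.cos(phi + beta - gamma_n) ** 2 + math.tan(eta_c) ** 2 * math.sin(beta) ** 2
    if d2 <= 1e-300:
        raise FloatingPointError("degenerate Armarego denominator (D -> 0)")
    D = math.sqrt(d2) if armarego_sqrt else d2

    ktc = tau * (math.cos(beta - gamma_n) + math.tan(eta_c) * math.tan(lam) * math.sin(beta)) / (
        math.sin(phi) * D
    )
    krc = tau * math.sin(beta - gamma_n) / (math.sin(phi) * math.cos(lam) * D)
    kac = tau * (math.cos(beta - gamma_n) * math.tan(lam) - math.tan(eta_c) * math.sin(beta)) / (
        math.sin(phi) * D
    )
    return ktc, krc, kac


def equivalent_rake_angle(h, geom: CutterGeometry):
    """Equivalent rake angle gamma_e (rad) of the blunt edge at chip thickness h.

    For ``h <= re (1 + sin gamma_n)`` the chip forms on the edge arc and

        gamma_e = arccos((re - h)/re) - pi/2,

    running from -pi/2 at h = 0 through 0 at h = re to gamma_n exactly at the
    branch point; above it the nominal rake governs. Vectorized over h.
    """
    re = geom.edge_radius
    gamma_n = geom.rake_angle
    h = np.asarray(h, dtype=float)
    if np.any(h < 0):
        raise ValueError("chip thickness must be nonnegative")
    h_star = re * (1.0 + math.sin(gamma_n))
    on_arc = h <= h_star
    arg = np.clip((re - np.where(on_arc, h, 0.0)) / re, -1.0, 1.0)
    gamma = np.where(on_arc, np.arccos(arg) - math.pi / 2, gamma_n)
    return gamma if gamma.ndim else float(gamma)


def ploughing_coefficients(
    mat: BoneMaterial,
    geom: CutterGeometry,
    direction: Union[Direction, int, str],
    h,
    *,
    slipline_length: str = "product",
) -> Tuple[np.ndarray, np.ndarray]:
    """Ploughing coefficients (Ktp, Krp) in N per metre of edge length.

    Slip-line angle eta = 0.5 arccos(mu); ploughed length l_MN = re sin(eta)
    (``slipline_length="quotient"`` switches to re/sin(eta), the alternative
    reading of the compact notation — roughly two orders of magnitude larger);
    ploughing force per unit width F_p/b = tau cos(2 eta) l_MN. The split is

        Ktp = (F_p/b) |sin gamma_e|,   Krp = (F_p/b) cos gamma_e,

    stored as nonnegative magnitudes (ploughing is resistive; the sense is
    applied in the force decomposition). Vectorized over h.
    """
    direction = Direction.coerce(direction)
    mu = mat.friction(direction)
    tau = mat.shear_strength(direction)
    eta = slip_line_angle(mu)
    if slipline_length == "product":
        l_mn = geom.edge_radius * math.sin(eta)
    elif slipline_length == "quotient":
        if math.sin(eta) == 0.0:
            raise ZeroDivisionError("slip-line angle is zero; quotient form undefined")
        l_mn = geom.edge_radius / math.sin(eta)
    else:
        raise ValueError(f"slipline_length must be 'product' or 'quotient', got {slipline_length!r}")
    fp_per_width = tau * math.cos(2 * eta) * l_mn
    gamma_e = np.asarray(equivalent_rake_angle(h, geom), dtype=float)
    ktp = fp_per_width * np.abs(np.sin(gamma_e))
    krp = fp_per_width * np.cos(gamma_e)
    if gamma_e.ndim == 0:
        return float(ktp), float(krp)
    return ktp, krp


def coefficient_set(
    mat: BoneMaterial,
    geom: CutterGeometry,
    direction,
    h: float,
    *,
    armarego_sqrt: bool = True,
    slipline_length: str = "product",
) -> CoefficientSet:
    """All five coefficients at one chip thickness (convenience wrapper)."""
    ktc, krc, kac = shear_coefficients(mat, geom, direction, armarego_sqrt=armarego_sqrt)
    ktp, krp = ploughing_coefficients(mat, geom, direction, h, slipline_length=slipline_length)
    return CoefficientSet(Ktc=ktc, Krc=krc, Kac=kac, Ktp=ktp, Krp=krp)
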