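"""Anisotropic shear properties of cortical bone.

Cortical bone behaves as a fibre-reinforced composite: osteons run along the
bone axis and give the tissue direction-dependent shear strength and friction.
Three cutting directions are distinguished by the orientation of the cutting
velocity relative to the osteon axis:

* ``PARALLEL`` (1) — cutting velocity along the osteon axis,
* ``CROSS`` (2) — cutting velocity across the osteon axis in the transverse
  plane,
* ``VERTICAL`` (3) — cutting velocity perpendicular to the osteon axis.

Each direction carries its own shear strength ``tau_s`` and tool–bone friction
coefficient ``mu``; every cutting-force coefficient downstream is built from
these two numbers plus the cutter geometry.

All quantities are SI internally (Pa, rad); configuration surfaces accept MPa
and degrees and convert at the boundary (see :mod:`osteomill.config`).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from enum import IntEnum
from typing import Mapping, Union

import pandas as pd

__all__ = [
    "Direction",
    "BoneMaterial",
    "ShearTestRecord",
    "shear_strength_from_test",
    "friction_angle",
    "slip_line_angle",
    "default_bone_material",
    "max_load_from_csv",
]


class Direction(IntEnum):
    """Cutting direction relative to the osteon axis (1/2/3 coding)."""

    PARALLEL = 1
    CROSS = 2
    VERTICAL = 3

    @classmethod
    def coerce(cls, value: Union["Direction", int, str]) -> "Direction":
        """Accept a Direction, its integer code, or a string alias."""
        if isinstance(value, cls):
            return value
        if isinstance(value, str):
            key = value.strip().lower()
            aliases = {
                "parallel": cls.PARALLEL,
                "cross": cls.CROSS,
                "across": cls.CROSS,
                "vertical": cls.VERTICAL,
            }
            if key in aliases:
                return aliases[key]
            if key.isdigit():
                value = int(key)
            else:
                raise ValueError(f"unknown cutting direction {value!r}")
        try:
            return cls(int(value))
        except ValueError as exc:
            raise ValueError(f"unknown cutting direction {value!r}") from exc


@dataclass(frozen=True)
class BoneMaterial:
    """Per-direction shear strength (Pa) and friction coefficient.

    Parameters
    ----------
    tau_s
        Shear strength in Pa, keyed by :class:`Direction`.
    mu
        Tool–bone friction coefficient (dimensionless, in (0, 1)), keyed by
        :class:`Direction`.
    """

    tau_s: Mapping[Direction, float]
    mu: Mapping[Direction, float]

    def __post_init__(self) -> None:
        tau = {Direction.coerce(k): float(v) for k, v in self.tau_s.items()}
        mu = {Direction.coerce(k): float(v) for k, v in self.mu.items()}
        for d in Direction:
            if d not in tau or d not in mu:
                raise ValueError(f"material must define all three directions; missing {d!r}")
        for d, v in tau.items():
            if not v > 0:
                raise ValueError(f"tau_s[{d}] must be positive, got {v}")
        for d, v in mu.items():
            if not 0 < v < 1:
                raise ValueError(f"mu[{d}] must lie in (0, 1), got {v}")
        object.__setattr__(self, "tau_s", tau)
        object.__setattr__(self, "mu", mu)

    def shear_strength(self, direction: Union[Direction, int, str]) -> float:
        return self.tau_s[Direction.coerce(direction)]

    def friction(self, direction: Union[Direction, int, str]) -> float:
        return self.mu[Direction.coerce(direction)]


@dataclass(frozen=True)
class ShearTestRecord:
    """One quasi-static shear test: peak load (N) over the shear plane (m^2)."""

    max_load: float
    shear_area: float
    direction: Direction = Direction.PARALLEL

    def __post_init__(self) -> None:
        if self.max_load < 0:
            raise ValueError(f"max_load must be nonnegative, got {self.max_load}")
        if not self.shear_area > 0:
            raise ValueError(f"shear_area must be positive, got {self.shear_area}")
        object.__setattr__(self, "direction", Direction.coerce(self.direction))


def shear_strength_from_test(rec: ShearTestRecord) -> float:
    """Shear strength (Pa) from a double-shear test: ``F_max / (2 S)``.

    The fixture shears the specimen over two planes simultaneously, hence the
    factor of two in the denominator.
    """
    return rec.max_load / (2.0 * rec.shear_area)


def friction_angle(mu: float) -> float:
    """Friction angle beta = arctan(mu), in (0, pi/2). Requires mu > 0."""
    if not mu > 0:
        raise ValueError(f"friction coefficient must be positive, got {mu}")
    return math.atan(mu)


def slip_line_angle(mu: float) -> float:
    """Slip-line field angle eta = 0.5 * arccos(mu), in [0, pi/4].

    Angle between the stagnation slip line under the blunt edge and the cut
    surface; mu = 1 collapses the field (eta = 0), mu = 0 opens it to 45 deg.
    """
    if not 0 <= mu <= 1:
        raise ValueError(f"friction coefficient must lie in [0, 1], got {mu}")
    return 0.5 * math.acos(mu)


def default_bone_material() -> BoneMaterial:
    """Bovine cortical bone defaults.

    Shear strengths from double-shear tests of fresh bovine femur (MPa:
    parallel 81.03, cross 94.48, vertical 180.12) and rake-face friction
    coefficients per direction (0.82 / 0.98 / 0.85).
    """
    return BoneMaterial(
        tau_s={
            Direction.PARALLEL: 81.03e6,
            Direction.CROSS: 94.48e6,
            Direction.VERTICAL: 180.12e6,
        },
        mu={
            Direction.PARALLEL: 0.82,
            Direction.CROSS: 0.98,
            Direction.VERTICAL: 0.85,
        },
    )


def max_load_from_csv(path) -> float:
    """Extract the peak load (N) from a displacement/load shear-test CSV.

    The file must have a header row with columns ``displacement_mm`` and
    ``load_N``; only the maximum load enters the strength calculation.
    """
    df = pd.read_csv(path)
    missing = {"displacement_mm", "load_N"} - set(df.columns)
    if missing:
        raise ValueError(f"shear-test CSV missing columns: {sorted(missing)}")
    if df.empty:
        raise ValueError("shear-test CSV has no data rows")
    return float(df["load_N"].max())
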