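"""Tool-tip and tool-centre trajectories in the workpiece frame.

The workpiece sits on a 2D vibration platform; folding the platform motion
into the tool-relative-to-workpiece trajectory, the tip of tooth ``j`` moves as

    x(t) = v t + r sin(w t - 2 pi j / N) + r0 sin(w t + psi) + Ax sin(2 pi fx t + phi_x)
    y(t) =       r cos(w t - 2 pi j / N) + r0 cos(w t + psi) + Ay sin(2 pi fy t + phi_y)

i.e. feed + rotation + spindle runout + platform vibration. The tooth-position
angle ``theta_j(t) = w t - 2 pi j / N`` is zero on the +Y axis and increases in
the rotation direction, so a tooth cuts the slot over ``theta mod 2pi`` in
[0, pi]. Angles are tracked unwrapped (they exceed 2 pi freely) and reduced
only for engagement tests.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Tuple

import numpy as np

from .materials import Direction
from .tooling import CutterGeometry

__all__ = [
    "VibrationParams",
    "ProcessParams",
    "phase_preset",
    "tip_position",
    "center_position",
    "tooth_angle",
    "time_grid",
]

#: Samples per period of the fastest process frequency in the default grid.
DEFAULT_SAMPLES_PER_CYCLE = 50


def phase_preset(name: str) -> Tuple[float, float]:
    """Initial phases (phi_x, phi_y) for the named signal-source preset.

    ``"sin-cos"`` drives Y a quarter period ahead of X (cos = sin(.+pi/2)),
    tracing an ellipse when amplitudes and frequencies match; ``"sin-sin"``
    drives both axes in phase (a diagonal line).
    """
    key = name.strip().lower().replace("–", "-").replace("_", "-")
    presets = {"sin-cos": (0.0, math.pi / 2), "sin-sin": (0.0, 0.0)}
    if key not in presets:
        raise ValueError(f"unknown phase preset {name!r}; expected 'sin-cos' or 'sin-sin'")
    return presets[key]


@dataclass(frozen=True)
class VibrationParams:
    """Platform vibration: amplitudes (m), frequencies (Hz), phases (rad)."""

    Ax: float = 0.0
    Ay: float = 0.0
    fx: float = 0.0
    fy: float = 0.0
    phix: float = 0.0
    phiy: float = 0.0

    def __post_init__(self) -> None:
        if self.Ax < 0 or self.Ay < 0:
            raise ValueError("vibration amplitudes must be nonnegative")
        if self.fx < 0 or self.fy < 0:
            raise ValueError("vibration frequencies must be nonnegative")

    @classmethod
    def from_preset(cls, amplitude: float, frequency: float, preset: str = "sin-cos"):
        """Equal-amplitude, equal-frequency X/Y vibration with a phase preset."""
        phix, phiy = phase_preset(preset)
        return cls(Ax=amplitude, Ay=amplitude, fx=frequency, fy=frequency, phix=phix, phiy=phiy)

    @property
    def off(self) -> bool:
        return self.Ax == 0.0 and self.Ay == 0.0


@dataclass(frozen=True)
class ProcessParams:
    """Milling process parameters (SI; spindle speed in rev/min).

    ``feed_speed`` (m/s) and ``omega`` (rad/s) are derived:
    v = fz N n / 60, omega = 2 pi n / 60.
    """

    spindle_speed: float  # rev/min
    feed_per_tooth: float  # m
    axial_depth: float  # m
    direction: Direction = Direction.PARALLEL
    n_flutes: int = 2

    def __post_init__(self) -> None:
        if not self.spindle_speed > 0:
            raise ValueError("spindle_speed must be positive")
        if self.feed_per_tooth < 0:
            raise ValueError("feed_per_tooth must be nonnegative")
        if not self.axial_depth > 0:
            raise ValueError("axial_depth must be positive")
        object.__setattr__(self, "direction", Direction.coerce(self.direction))

    @property
    def omega(self) -> float:
        """Spindle angular velocity (rad/s)."""
        return 2 * math.pi * self.spindle_speed / 60.0

    @property
    def feed_speed(self) -> float:
        """Feed speed v = fz * N * n / 60 (m/s)."""
        return self.feed_per_tooth * self.n_flutes * self.spindle_speed / 60.0

    @property
    def rev_period(self) -> float:
        """Time of one spindle revolution (s)."""
        return 60.0 / self.spindle_speed

    @property
    def tooth_period(self) -> float:
        """Time between successive tooth passes (s)."""
        return self.rev_period / self.n_flutes

    @property
    def tooth_passing_frequency(self) -> float:
        return self.n_flutes * self.spindle_speed / 60.0


def default_process(direction=Direction.PARALLEL) -> ProcessParams:
    """Study defaults: 3000 rev/min, 10 um/tooth, 100 um axial depth, 2 flutes."""
    return ProcessParams(
        spindle_speed=3000.0,
        feed_per_tooth=10e-6,
        axial_depth=100e-6,
        direction=direction,
        n_flutes=2,
    )


def tooth_angle(t, j: int, proc: ProcessParams):
    """Unwrapped tooth-position angle theta_j(t) = omega t - 2 pi j / N."""
    return proc.omega * np.asarray(t, dtype=float) - 2 * math.pi * j / proc.n_flutes


def tip_position(t, j: int, geom: CutterGeometry, vib: VibrationParams, proc: ProcessParams):
    """Tip of tooth ``j`` relative to the workpiece at time(s) t; returns (x, y) in m."""
    t = np.asarray(t, dtype=float)
    ang = proc.omega * t - 2 * math.pi * j / proc.n_flutes
    xo, yo = center_position(t, geom, vib, proc)
    return xo + geom.radius * np.sin(ang), yo + geom.radius * np.cos(ang)


def center_position(t, geom: CutterGeometry, vib: VibrationParams, proc: ProcessParams):
    """Tool-centre trajectory (feed + runout + vibration); returns (x, y) in m."""
    t = np.asarray(t, dtype=float)
    run = proc.omega * t + geom.runout_angle
    x = (
        proc.feed_speed * t
        + geom.runout * np.sin(run)
        + vib.Ax * np.sin(2 * math.pi * vib.fx * t + vib.phix)
    )
    y = geom.runout * np.cos(run) + vib.Ay * np.sin(2 * math.pi * vib.fy * t + vib.phiy)
    return x, y


def time_grid(
    vib: VibrationParams,
    proc: ProcessParams,
    n_revolutions: int,
    samples_per_cycle: int = DEFAULT_SAMPLES_PER_CYCLE,
) -> Tuple[np.ndarray, float]:
    """Uniform simulation grid over ``n_revolutions`` spindle revolutions.

    The step resolves the fastest of (fx, fy, tooth-passing frequency) with
    ``samples_per_cycle`` samples per period, rounded so that a revolution
    holds an integer number of steps (whole-revolution RMS windows need this).
    Returns (t, dt); t starts at 0 and excludes the right endpoint.
    """
    f_max = max(vib.fx, vib.fy, proc.tooth_passing_frequency)
    dt_target = 1.0 / (samples_per_cycle * f_max)
    steps_per_rev = max(int(math.ceil(proc.rev_period / dt_target)), 8)
    dt = proc.rev_period / steps_per_rev
    n = steps_per_rev * int(n_revolutions)
    return np.arange(n) * dt, dt
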