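"""Single-factor experiment grid, signal conditioning and RMS summaries.

The study design is a 14-group single-factor grid over cutting direction,
vibration amplitude and vibration frequency, at fixed spindle speed
3000 rev/min, feed 10 um/tooth, axial depth 100 um and a sin–cos drive:

* groups 1–3: conventional milling (A = 0, f = 0), directions 1/2/3;
* groups 4–6: A = 1 um, f = 3000 Hz, directions 1/2/3;
* groups 7–11: direction 1, f = 3000 Hz, A in {0.5, 1.5, 2, 2.5, 3} um;
* groups 12–14: direction 1, A = 1.5 um, f in {1000, 2000, 4000} Hz.

Force traces are conditioned the way dynamometer records are: a zero-phase
low-pass at 120 Hz, then RMS over whole steady-state revolutions, and percent
change against the conventional baseline of the same cutting direction.
A seeded synthetic "experimental" trace generator (model output + Gaussian
noise, resampled to a dynamometer rate) keeps the comparison pipeline
testable without hardware data.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Dict, Iterable, List, Optional, Tuple

import numpy as np
import pandas as pd
from scipy.signal import butter, sosfiltfilt

from .chip import ThicknessProfile, thickness_profile
from .forces import ForceTrace, simulate
from .kinematics import ProcessParams, VibrationParams
from .materials import BoneMaterial, Direction, default_bone_material
from .tooling import CutterGeometry, default_cutter

__all__ = [
    "ExperimentSpec",
    "RmsSummary",
    "single_factor_grid",
    "lowpass_filter",
    "rms",
    "run_sweep",
    "synth_experimental_trace",
    "compare_traces",
    "SWEEP_GROUPS",
]

#: experiment groups (1-based ids) forming each single-factor sweep
SWEEP_GROUPS = {
    "direction": [4, 5, 6],
    "amplitude": [1, 4, 7, 8, 9, 10, 11],
    "frequency": [1, 8, 12, 13, 14],
}


@dataclass(frozen=True)
class ExperimentSpec:
    """One grid row: direction, vibration amplitude (m) and frequency (Hz).

    Conventional milling is encoded as amplitude = frequency = 0. The fixed
    block (3000 rev/min, 10 um/tooth, 100 um depth, sin–cos phases) is
    materialised by :meth:`process` / :meth:`vibration`.
    """

    id: int
    direction: Direction
    amplitude: float
    frequency: float

    def __post_init__(self) -> None:
        object.__setattr__(self, "direction", Direction.coerce(self.direction))
        if (self.amplitude == 0.0) != (self.frequency == 0.0):
            raise ValueError("conventional milling requires amplitude = 0 AND frequency = 0")

    @property
    def conventional(self) -> bool:
        return self.amplitude == 0.0

    def vibration(self, preset: str = "sin-cos") -> VibrationParams:
        if self.conventional:
            return VibrationParams()
        return VibrationParams.from_preset(self.amplitude, self.frequency, preset)

    def process(
        self,
        spindle_speed: float = 3000.0,
        feed_per_tooth: float = 10e-6,
        axial_depth: float = 100e-6,
        n_flutes: int = 2,
    ) -> ProcessParams:
        return ProcessParams(
            spindle_speed=spindle_speed,
            feed_per_tooth=feed_per_tooth,
            axial_depth=axial_depth,
            direction=self.direction,
            n_flutes=n_flutes,
        )


def single_factor_grid() -> List[ExperimentSpec]:
    """The 14-row single-factor grid (amplitudes in m, frequencies in Hz)."""
    um = 1e-6
    rows: List[Tuple[int, int, float, float]] = [
        (1, 1, 0.0, 0.0),
        (2, 2, 0.0, 0.0),
        (3, 3, 0.0, 0.0),
        (4, 1, 1 * um, 3000.0),
        (5, 2, 1 * um, 3000.0),
        (6, 3, 1 * um, 3000.0),
        (7, 1, 0.5 * um, 3000.0),
        (8, 1, 1.5 * um, 3000.0),
        (9, 1, 2 * um, 3000.0),
        (10, 1, 2.5 * um, 3000.0),
        (11, 1, 3 * um, 3000.0),
        (12, 1, 1.5 * um, 1000.0),
        (13, 1, 1.5 * um, 2000.0),
        (14, 1, 1.5 * um, 4000.0),
    ]
    return [ExperimentSpec(i, d, a, f) for i, d, a, f in rows]


def lowpass_filter(trace: ForceTrace, cutoff: float = 120.0, order: int = 4) -> ForceTrace:
    """Zero-phase Butterworth low-pass of all three force channels.

    Applied forward-backward (second-order sections), so the pass band keeps
    unit gain and zero phase lag — overlaying filtered model and experiment
    traces stays time-aligned. ``cutoff`` must be below the trace Nyquist.
    """
    nyq = 0.5 * trace.sample_rate
    if not 0 < cutoff < nyq:
        raise ValueError(f"cutoff {cutoff} Hz must lie in (0, Nyquist={nyq} Hz)")
    sos = butter(order, cutoff, btype="low", fs=trace.sample_rate, output="sos")
    return trace.replace_forces(
        Fx=sosfiltfilt(sos, trace.Fx),
        Fy=sosfiltfilt(sos, trace.Fy),
        Fz=sosfiltfilt(sos, trace.Fz),
        filter_cutoff_hz=cutoff,
        filter_order=order,
    )


def rms(values) -> float:
    """Root-mean-square, sqrt(mean(x^2)); input must be nonempty."""
    values = np.asarray(values, dtype=float)
    if values.size == 0:
        raise ValueError("rms of an empty array is undefined")
    return float(np.sqrt(np.mean(values**2)))


@dataclass(frozen=True)
class RmsSummary:
    """Filtered-force RMS of one experiment and change vs its baseline."""

    id: int
    direction: Direction
    amplitude: float
    frequency: float
    rms_fx: float
    rms_fy: float
    pct_change_fx: Optional[float] = None
    pct_change_fy: Optional[float] = None


def _percent_change(value: float, baseline: float) -> float:
    return (value - baseline) / baseline * 100.0


def run_sweep(
    axis: str,
    specs: Optional[Iterable[ExperimentSpec]] = None,
    *,
    mat: Optional[BoneMaterial] = None,
    geom: Optional[CutterGeometry] = None,
    n_revolutions: int = 4,
    cutoff: float = 120.0,
    phase_preset: str = "sin-cos",
    **model_opts,
) -> pd.DataFrame:
    """Simulate a single-factor sweep and summarise filtered RMS forces.

    ``axis`` selects the grid subset (``direction``, ``amplitude`` or
    ``frequency``); explicit ``specs`` override it. Conventional baselines of
    every direction present are simulated alongside, and percent change
    ``(RMS_vib - RMS_conv) / RMS_conv * 100`` is reported per direction.
    Thickness profiles are cached across specs sharing kinematics (direction
    changes material properties only), so the direction sweep costs a single
    implicit solve.
    """
    if specs is None:
        if axis not in SWEEP_GROUPS:
            raise ValueError(f"axis must be one of {sorted(SWEEP_GROUPS)}, got {axis!r}")
        grid = {s.id: s for s in single_factor_grid()}
        specs = [grid[i] for i in SWEEP_GROUPS[axis]]
    specs = list(specs)
    mat = mat or default_bone_material()
    geom = geom or default_cutter()

    # ensure a conventional baseline per direction involved
    grid = {s.id: s for s in single_factor_grid()}
    directions = {s.direction for s in specs}
    baseline_specs = {d: grid[int(d)] for d in directions}  # groups 1-3 are directions 1-3
    all_specs = list({s.id: s for s in [*baseline_specs.values(), *specs]}.values())

    cache: Dict[Tuple, ThicknessProfile] = {}
    results: Dict[int, RmsSummary] = {}
    for spec in sorted(all_specs, key=lambda s: s.id):
        vib = spec.vibration(phase_preset)
        proc = spec.process()
        key = (vib.Ax, vib.Ay, vib.fx, vib.fy, vib.phix, vib.phiy)
        if key not in cache:
            cache[key] = thickness_profile(geom, vib, proc, n_revolutions)
        trace = simulate(
            mat, geom, vib, proc, n_revolutions, profile=cache[key], **model_opts
        )
        filt = lowpass_filter(trace, cutoff)
        results[spec.id] = RmsSummary(
            id=spec.id,
            direction=spec.direction,
            amplitude=spec.amplitude,
            frequency=spec.frequency,
            rms_fx=rms(filt.Fx),
            rms_fy=rms(filt.Fy),
        )

    rows = []
    for spec in sorted(all_specs, key=lambda s: s.id):
        r = results[spec.id]
        base = results[int(spec.direction)]
        pct_fx = pct_fy = None
        if not spec.conventional:
            pct_fx = _percent_change(r.rms_fx, base.rms_fx)
            pct_fy = _percent_change(r.rms_fy, base.rms_fy)
        rows.append(
            {
                "id": r.id,
                "direction": int(r.direction),
                "amplitude_um": r.amplitude * 1e6,
                "frequency_Hz": r.frequency,
                "rms_fx_N": r.rms_fx,
                "rms_fy_N": r.rms_fy,
                "pct_change_fx": pct_fx,
                "pct_change_fy": pct_fy,
            }
        )
    return pd.DataFrame(rows)


def synth_experimental_trace(
    trace: ForceTrace,
    noise_sd: float,
    seed: int,
    sample_rate: float = 10000.0,
) -> ForceTrace:
    """Synthetic dynamometer record: model trace + white noise at a fixed rate.

    Resamples the model trace to ``sample_rate`` by linear interpolation and
    adds independent seeded Gaussian noise per channel — a stand-in for
    hardware force records so the model-vs-experiment comparison pipeline runs
    offline. Deterministic for a given seed.
    """
    if noise_sd < 0:
        raise ValueError("noise_sd must be nonnegative")
    if noise_sd == 0.0 and sample_rate == trace.sample_rate:
        return trace
    rng = np.random.default_rng(seed)
    t_new = np.arange(trace.t[0], trace.t[-1], 1.0 / sample_rate)
    out = {}
    for name in ("Fx", "Fy", "Fz"):
        resampled = np.interp(t_new, trace.t, getattr(trace, name))
        out[name] = resampled + rng.normal(0.0, noise_sd, t_new.size) if noise_sd else resampled
    theta = np.interp(t_new, trace.t, trace.theta)
    params = dict(trace.params)
    params.update({"synthetic": True, "noise_sd_N": noise_sd, "seed": seed})
    return ForceTrace(t=t_new, theta=theta, Fx=out["Fx"], Fy=out["Fy"], Fz=out["Fz"], params=params)


def compare_traces(
    model: ForceTrace, experiment: ForceTrace, cutoff: float = 120.0
) -> Dict[str, float]:
    """Filtered-RMS comparison of a model trace against a measured trace.

    The experimental record is linearly resampled onto the model grid, both
    are low-passed at ``cutoff`` and RMS values plus percent errors
    ``(model - experiment) / experiment * 100`` are reported per channel.
    """
    exp_on_model = ForceTrace(
        t=model.t,
        theta=model.theta,
        Fx=np.interp(model.t, experiment.t, experiment.Fx),
        Fy=np.interp(model.t, experiment.t, experiment.Fy),
        Fz=np.interp(model.t, experiment.t, experiment.Fz),
        params=dict(experiment.params),
    )
    fm = lowpass_filter(model, cutoff)
    fe = lowpass_filter(exp_on_model, cutoff)
    out: Dict[str, float] = {}
    for name in ("Fx", "Fy"):
        rm = rms(getattr(fm, name))
        re_ = rms(getattr(fe, name))
        out[f"rms_model_{name.lower()}_N"] = rm
        out[f"rms_experiment_{name.lower()}_N"] = re_
        out[f"pct_error_{name.lower()}"] = _percent_change(rm, re_)
    return out
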