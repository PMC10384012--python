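"""Configuration loading with field-unit boundaries.

Config files (YAML or JSON) speak the units practitioners use — MPa, um, deg,
rev/min, Hz — and are converted to SI here, once, at the boundary. Blocks:

.. code-block:: yaml

    material:
      parallel: {tau_s_MPa: 81.03, mu: 0.82}
      cross:    {tau_s_MPa: 94.48, mu: 0.98}
      vertical: {tau_s_MPa: 180.12, mu: 0.85}
    cutter:
      diameter_um: 800
      rake_deg: 5
      clearance_deg: 10
      helix_deg: 35
      edge_radius_um: 5
      runout_um: 2
      runout_angle_deg: 0
      n_flutes: 2
    vibration:
      Ax_um: 1
      Ay_um: 1
      fx_Hz: 3000
      fy_Hz: 3000
      phase_preset: sin-cos   # or phix_deg / phiy_deg
    process:
      spindle_rpm: 3000
      feed_per_tooth_um: 10
      axial_depth_um: 100
      direction: 1            # 1/2/3 or parallel/cross/vertical

Every block is optional; omitted blocks fall back to the study defaults.
"""

from __future__ import annotations

import json
import math
from pathlib import Path
from typing import Any, Dict, Tuple

import yaml

from .kinematics import ProcessParams, VibrationParams, phase_preset
from .materials import BoneMaterial, Direction, default_bone_material
from .tooling import CutterGeometry, default_cutter

__all__ = ["load_config", "parse_config", "default_config_dict"]

UM = 1e-6
MPA = 1e6


def default_config_dict() -> Dict[str, Any]:
    """The study defaults, in boundary units, as a plain dict."""
    return {
        "material": {
            "parallel": {"tau_s_MPa": 81.03, "mu": 0.82},
            "cross": {"tau_s_MPa": 94.48, "mu": 0.98},
            "vertical": {"tau_s_MPa": 180.12, "mu": 0.85},
        },
        "cutter": {
            "diameter_um": 800,
            "rake_deg": 5,
            "clearance_deg": 10,
            "helix_deg": 35,
            "edge_radius_um": 5,
            "runout_um": 2,
            "runout_angle_deg": 0,
            "n_flutes": 2,
        },
        "vibration": {"Ax_um": 0, "Ay_um": 0, "fx_Hz": 0, "fy_Hz": 0, "phase_preset": "sin-cos"},
        "process": {
            "spindle_rpm": 3000,
            "feed_per_tooth_um": 10,
            "axial_depth_um": 100,
            "direction": 1,
        },
        "model": {},
    }


def _parse_material(block: Dict[str, Any]) -> BoneMaterial:
    tau, mu = {}, {}
    for key, entry in block.items():
        d = Direction.coerce(key)
        tau[d] = float(entry["tau_s_MPa"]) * MPA
        mu[d] = float(entry["mu"])
    return BoneMaterial(tau_s=tau, mu=mu)


def _parse_cutter(block: Dict[str, Any]) -> CutterGeometry:
    return CutterGeometry(
        radius=float(block["diameter_um"]) * UM / 2,
        rake_angle=math.radians(float(block["rake_deg"])),
        clearance_angle=math.radians(float(block["clearance_deg"])),
        helix_angle=math.radians(float(block["helix_deg"])),
        edge_radius=float(block["edge_radius_um"]) * UM,
        runout=float(block.get("runout_um", 0.0)) * UM,
        runout_angle=math.radians(float(block.get("runout_angle_deg", 0.0))),
        n_flutes=int(block.get("n_flutes", 2)),
    )


def _parse_vibration(block: Dict[str, Any]) -> VibrationParams:
    if "phase_preset" in block:
        phix, phiy = phase_preset(block["phase_preset"])
    else:
        phix = math.radians(float(block.get("phix_deg", 0.0)))
        phiy = math.radians(float(block.get("phiy_deg", 0.0)))
    return VibrationParams(
        Ax=float(block.get("Ax_um", 0.0)) * UM,
        Ay=float(block.get("Ay_um", 0.0)) * UM,
        fx=float(block.get("fx_Hz", 0.0)),
        fy=float(block.get("fy_Hz", 0.0)),
        phix=phix,
        phiy=phiy,
    )


def _parse_process(block: Dict[str, Any], n_flutes: int) -> ProcessParams:
    return ProcessParams(
        spindle_speed=float(block["spindle_rpm"]),
        feed_per_tooth=float(block["feed_per_tooth_um"]) * UM,
        axial_depth=float(block["axial_depth_um"]) * UM,
        direction=Direction.coerce(block.get("direction", 1)),
        n_flutes=n_flutes,
    )


def parse_config(
    cfg: Dict[str, Any],
) -> Tuple[BoneMaterial, CutterGeometry, VibrationParams, ProcessParams, Dict[str, Any]]:
    """Convert a config dict to model objects; missing blocks use defaults.

    The fifth element collects model options (``armarego_sqrt``,
    ``slipline_length``, ``n_slices``, ``ploughing``, ``flip_y``,
    ``n_revolutions``) passed through to the simulation.
    """
    base = default_config_dict()
    mat = _parse_material(cfg["material"]) if "material" in cfg else default_bone_material()
    geom = _parse_cutter({**base["cutter"], **cfg.get("cutter", {})}) if "cutter" in cfg else default_cutter()
    vib = _parse_vibration(cfg.get("vibration", base["vibration"]))
    proc = _parse_process({**base["process"], **cfg.get("process", {})}, geom.n_flutes)
    return mat, geom, vib, proc, dict(cfg.get("model", {}))


def load_config(path) -> Tuple[BoneMaterial, CutterGeometry, VibrationParams, ProcessParams, Dict[str, Any]]:
    """Load a YAML or JSON configuration file."""
    path = Path(path)
    text = path.read_text()
    cfg = json.loads(text) if path.suffix.lower() == ".json" else yaml.safe_load(text)
    if cfg is None:
        cfg = {}
    if not isinstance(cfg, dict):
        raise ValueError(f"config root must be a mapping, got {type(cfg).__name__}")
    return parse_config(cfg)
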