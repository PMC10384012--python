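import math

import pytest

import osteomill as om


@pytest.fixture(scope="session")
def material():
    return om.default_bone_material()


@pytest.fixture(scope="session")
def cutter():
    return om.default_cutter()


@pytest.fixture(scope="session")
def cutter_no_runout():
    g = om.default_cutter()
    return om.CutterGeometry(
        radius=g.radius,
        rake_angle=g.rake_angle,
        clearance_angle=g.clearance_angle,
        helix_angle=g.helix_angle,
        edge_radius=g.edge_radius,
        runout=0.0,
        n_flutes=g.n_flutes,
    )


@pytest.fixture(scope="session")
def process():
    return om.default_process()


@pytest.fixture(scope="session")
def no_vibration():
    return om.VibrationParams()


@pytest.fixture(scope="session")
def vibration_sincos():
    """Study vibration setting of the thickness figures: 2 um, 3 kHz, sin-cos."""
    return om.VibrationParams.from_preset(2e-6, 3000.0, "sin-cos")


@pytest.fixture(scope="session")
def conventional_profile(cutter_no_runout, no_vibration, process):
    """Steady conventional-milling thickness profile (no runout, no vibration)."""
    return om.thickness_profile(cutter_no_runout, no_vibration, process, 4)
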