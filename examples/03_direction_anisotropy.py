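"""Anisotropy of cutting force across the three osteon-relative directions.

Cortical bone shears hardest across the osteon axis: shear strength rises
from 81.03 MPa (parallel) through 94.48 MPa (cross) to 180.12 MPa (vertical).
The thickness solve is purely kinematic, so one profile serves all three
directions and only the coefficient weighting changes.
"""

import osteomill as om

mat = om.default_bone_material()
geom = om.default_cutter()
vib = om.VibrationParams.from_preset(1e-6, 3000.0, "sin-cos")

profile = om.thickness_profile(geom, vib, om.default_process(), 4)

print(f"{'direction':<10} {'tau_s MPa':>10} {'mu':>6} {'RMS Fx N':>10} {'RMS Fy N':>10}")
for d in (1, 2, 3):
    proc = om.ProcessParams(3000.0, 10e-6, 100e-6, direction=d)
    trace = om.simulate(mat, geom, vib, proc, 4, profile=profile)
    filt = om.lowpass_filter(trace)
    name = om.Direction(d).name.lower()
    print(
        f"{name:<10} {mat.shear_strength(d) / 1e6:>10.2f} {mat.friction(d):>6.2f} "
        f"{om.rms(filt.Fx):>10.4f} {om.rms(filt.Fy):>10.4f}"
    )

print(
    "\nVertical cutting (velocity perpendicular to the osteons) produces the"
    "\nlargest force, cross is intermediate, parallel the smallest — the RMS"
    "\nordering tracks the anisotropic shear strengths."
)
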