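"""Resolve instantaneous chip thickness: conventional vs vibration-assisted.

Builds the default 0.8 mm two-flute cutter at 3000 rev/min, 10 um/tooth, and
resolves one steady revolution of uncut chip thickness twice: without
vibration (smooth trochoidal chip, peak ~ fz plus the runout split) and with
a 2 um / 3 kHz sin–cos platform vibration (oscillating chip with
tool–workpiece separation intervals).
"""

import math

import numpy as np

import osteomill as om

geom = om.default_cutter()
proc = om.default_process()

for label, vib in [
    ("conventional", om.VibrationParams()),
    ("vibration 2 um / 3 kHz", om.VibrationParams.from_preset(2e-6, 3000.0, "sin-cos")),
]:
    prof = om.thickness_profile(geom, vib, proc, 3)
    spr = prof.steps_per_revolution
    print(f"\n--- {label} ---")
    for j in range(prof.n_flutes):
        th = np.mod(prof.theta[j][spr:2 * spr], 2 * math.pi)
        h = prof.h[j][spr:2 * spr]
        seg = h[th <= math.pi]
        peaks = int(np.sum((seg[1:-1] > seg[:-2]) & (seg[1:-1] > seg[2:]) & (seg[1:-1] > 0)))
        print(
            f"tooth {j}: peak h = {seg.max() * 1e6:6.2f} um, "
            f"separation = {100 * np.mean(seg == 0):5.1f} % of arc, "
            f"local maxima per arc = {peaks}"
        )

print(
    "\nPeak thickness differs between the two flutes (2 um spindle runout ->"
    "\nlong/short-tooth cutting); vibration turns the smooth chip into ~30"
    "\noscillations per arc (3000 Hz / 100 Hz tooth passing) with empty-cut"
    "\nintervals where the edge separates from the bone."
)
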