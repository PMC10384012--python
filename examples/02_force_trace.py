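"""Simulate a vibration-assisted milling force trace and summarise it.

Runs the full pipeline (kinematics -> chip thickness -> coefficient-weighted
micro-element integration) for parallel-direction cutting of bovine cortical
bone under a 1 um / 3 kHz vibration, low-passes the trace at 120 Hz the way
dynamometer records are conditioned, and prints peak and RMS forces.
"""

import numpy as np

import osteomill as om

mat = om.default_bone_material()
geom = om.default_cutter()
proc = om.default_process(direction=1)
vib = om.VibrationParams.from_preset(1e-6, 3000.0, "sin-cos")

trace = om.simulate(mat, geom, vib, proc, n_revolutions=4)
filt = om.lowpass_filter(trace, cutoff=120.0)

print(f"samples: {trace.t.size} over {trace.t[-1] - trace.t[0]:.4f} s "
      f"(dt = {trace.dt * 1e6:.2f} us)")
print(f"raw      peak |Fx| = {np.abs(trace.Fx).max():.3f} N, "
      f"peak |Fy| = {np.abs(trace.Fy).max():.3f} N")
print(f"filtered RMS  Fx  = {om.rms(filt.Fx):.4f} N, RMS Fy = {om.rms(filt.Fy):.4f} N")

# the vibration imprints itself on the spectrum near its drive frequency
sp = np.abs(np.fft.rfft(trace.Fx - trace.Fx.mean()))
fr = np.fft.rfftfreq(trace.t.size, trace.dt)
band = (fr > 2800) & (fr < 3200)
print(f"spectral amplitude near 3 kHz / global peak = {sp[band].max() / sp.max():.3f}")

print(
    "\nThe filtered RMS values are the model's summary statistic per cutting"
    "\ncondition; the 3 kHz spectral line is the vibration drive showing"
    "\nthrough the tooth-passing envelope."
)
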