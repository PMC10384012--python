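import math

import numpy as np
import pytest

import osteomill as om

from oracles import armarego_coefficients, waldorf_ploughing


class TestElementalForces:
    def test_zero_thickness_transmits_nothing(self, material, cutter):
        coeffs = om.coefficient_set(material, cutter, 1, 0.0)
        assert om.elemental_forces(0.0, 5e-6, coeffs) == (0.0, 0.0, 0.0)

    def test_linearity_in_slice_height(self, material, cutter):
        coeffs = om.coefficient_set(material, cutter, 2, 8e-6)
        f1 = om.elemental_forces(8e-6, 5e-6, coeffs)
        f2 = om.elemental_forces(8e-6, 10e-6, coeffs)
        assert f2 == pytest.approx(tuple(2 * v for v in f1), rel=1e-14)

    def test_matches_reference_evaluation(self, material, cutter):
        """h = 10 um, dz = 5 um, direction 1: spreadsheet-style recomputation."""
        h, dz = 10e-6, 5e-6
        coeffs = om.coefficient_set(material, cutter, 1, h)
        ktc, krc, kac = armarego_coefficients(81.03e6, 0.82, cutter.rake_angle, cutter.helix_angle)
        ktp, krp = waldorf_ploughing(81.03e6, 0.82, cutter.edge_radius, cutter.rake_angle, h)
        want = (ktc * h * dz + ktp * dz, krc * h * dz + krp * dz, kac * h * dz)
        assert om.elemental_forces(h, dz, coeffs) == pytest.approx(want, rel=1e-12)

    def test_invalid_inputs_rejected(self, material, cutter):
        coeffs = om.coefficient_set(material, cutter, 1, 1e-6)
        with pytest.raises(ValueError):
            om.elemental_forces(-1e-6, 5e-6, coeffs)
        with pytest.raises(ValueError):
            om.elemental_forces(1e-6, 0.0, coeffs)


class TestAssembleForces:
    def test_zero_strength_zero_trace(self, cutter, no_vibration, process, conventional_profile):
        """tau = 0 (approximated by a vanishing strength) with ploughing off
        produces an identically zero force trace."""
        tiny = om.BoneMaterial(
            tau_s={1: 1e-300, 2: 1e-300, 3: 1e-300}, mu={1: 0.82, 2: 0.98, 3: 0.85}
        )
        trace = om.assemble_forces(conventional_profile, conventional_profile.geom, process, tiny,
                                   ploughing=False)
        assert np.abs(trace.Fx).max() < 1e-290
        assert np.abs(trace.Fy).max() < 1e-290
        assert np.abs(trace.Fz).max() < 1e-290

    def test_single_element_rotation_identity(self, material, cutter, no_vibration):
        """With a single slice and negligible helix wrap the assembly reduces to
        the planar rotation of one micro-element at the tooth angle."""
        proc = om.ProcessParams(3000.0, 10e-6, 1e-6, 1, 2)  # H -> 0: one thin slice
        geom = om.CutterGeometry(
            radius=400e-6, rake_angle=math.radians(5), clearance_angle=math.radians(10),
            helix_angle=math.radians(35), edge_radius=5e-6, runout=0.0,
        )
        prof = om.thickness_profile(geom, no_vibration, proc, 3)
        trace = om.assemble_forces(prof, geom, proc, material, n_slices=1)
        spr = prof.steps_per_revolution
        k = spr * 2 + spr // 4  # steady state, theta ~ pi/2
        lag = math.tan(geom.helix_angle) * (0.5e-6) / geom.radius
        theta = math.radians(trace.theta[k]) - lag
        t_lag = prof.t[k] - lag / proc.omega
        h = float(np.interp(t_lag, prof.t, prof.h[0]))
        coeffs = om.coefficient_set(material, geom, 1, h)
        dft, dfr, dfa = om.elemental_forces(h, 1e-6, coeffs)
        want_fx = dft * math.cos(theta) + dfr * math.sin(theta)
        want_fy = -dft * math.sin(theta) + dfr * math.cos(theta)
        # tooth 1 is half a turn away (not engaged) so one element dominates
        assert trace.Fx[k] == pytest.approx(want_fx, rel=1e-9)
        assert trace.Fy[k] == pytest.approx(want_fy, rel=1e-9)
        assert trace.Fz[k] == pytest.approx(-dfa, rel=1e-9)

    def test_engagement_consistency(self, material, process, conventional_profile):
        """Force vanishes exactly where no slice of any flute carries material:
        a slice at height z sees the tip thickness lagged by theta_z/omega, so
        the force at time t can only be nonzero if some tooth had h > 0 within
        the helix-lag window [t - lag/omega, t]."""
        geom = conventional_profile.geom
        prof = conventional_profile
        trace = om.assemble_forces(prof, geom, process, material)
        lag_total = om.lag_angle(geom, process.axial_depth)
        w = int(math.ceil(lag_total / process.omega / prof.dt)) + 1
        f = np.abs(trace.Fx) + np.abs(trace.Fy) + np.abs(trace.Fz)
        any_h = prof.h.max(axis=0) > 0.0
        recent = np.convolve(any_h.astype(float), np.ones(w + 1), mode="full")[: f.size]
        assert np.all(f[recent == 0.0] == 0.0)
        # and conversely: strictly inside a chip arc the force is nonzero
        spr = prof.steps_per_revolution
        mid = 2 * spr + spr // 4  # steady state, tooth 0 at theta ~ pi/2
        assert f[mid] > 0.0

    def test_direction_ordering_rms(self, material, cutter, process):
        """Vertical > cross > parallel force RMS under 1 um / 3 kHz vibration."""
        vib = om.VibrationParams.from_preset(1e-6, 3000.0, "sin-cos")
        prof = om.thickness_profile(cutter, vib, process, 3)
        rms_by_dir = {}
        for d in (1, 2, 3):
            proc = om.ProcessParams(3000.0, 10e-6, 100e-6, d, 2)
            trace = om.simulate(material, cutter, vib, proc, 3, profile=prof)
            filt = om.lowpass_filter(trace)
            rms_by_dir[d] = (om.rms(filt.Fx), om.rms(filt.Fy))
        for axis in (0, 1):
            assert rms_by_dir[3][axis] > rms_by_dir[2][axis] > rms_by_dir[1][axis]

    def test_linearity_in_strength_without_ploughing(self, material, process, conventional_profile):
        geom = conventional_profile.geom
        c = 3.0
        scaled = om.BoneMaterial(
            tau_s={d: c * v for d, v in material.tau_s.items()}, mu=dict(material.mu)
        )
        t1 = om.assemble_forces(conventional_profile, geom, process, material, ploughing=False)
        t2 = om.assemble_forces(conventional_profile, geom, process, scaled, ploughing=False)
        assert t2.Fx == pytest.approx(c * t1.Fx, rel=1e-12)
        assert t2.Fy == pytest.approx(c * t1.Fy, rel=1e-12)

    def test_axial_slice_convergence(self, material, process, conventional_profile):
        """Doubling the slice count changes the RMS by < 0.5 %."""
        geom = conventional_profile.geom
        r20 = om.rms(om.assemble_forces(conventional_profile, geom, process, material,
                                        n_slices=20).Fx)
        r40 = om.rms(om.assemble_forces(conventional_profile, geom, process, material,
                                        n_slices=40).Fx)
        assert abs(r40 - r20) / r20 < 0.005

    def test_slice_heights_reproduce_axial_depth(self, process, cutter):
        """Sum of dz over slices equals H; via the helix relation the angular
        wrap maps back to the same depth."""
        n = 20
        dz = process.axial_depth / n
        assert n * dz == pytest.approx(process.axial_depth, rel=1e-12)
        dtheta = math.tan(cutter.helix_angle) * dz / cutter.radius
        depth_back = n * dtheta * cutter.radius / math.tan(cutter.helix_angle)
        assert depth_back == pytest.approx(process.axial_depth, rel=1e-9)


class TestSimulate:
    def test_determinism(self, material, cutter, process):
        vib = om.VibrationParams.from_preset(1e-6, 3000.0)
        a = om.simulate(material, cutter, vib, process, 3)
        b = om.simulate(material, cutter, vib, process, 3)
        assert np.array_equal(a.Fx, b.Fx) and np.array_equal(a.Fy, b.Fy)
        assert np.array_equal(a.t, b.t)

    def test_discards_startup_revolution(self, material, cutter, process, no_vibration):
        trace = om.simulate(material, cutter, no_vibration, process, 3)
        assert trace.t[0] >= process.rev_period * (1 - 1e-9)

    def test_vibration_spectral_peak(self, material, cutter, process):
        """1 um / 3 kHz vibration imprints spectral content near 3 kHz that
        conventional milling lacks."""
        vib = om.VibrationParams.from_preset(1e-6, 3000.0)
        tr_v = om.simulate(material, cutter, vib, process, 4)
        prof = om.thickness_profile(cutter, om.VibrationParams(), process, 4,
                                    dt=tr_v.t[1] - tr_v.t[0])
        tr_c = om.simulate(material, cutter, om.VibrationParams(), process, 4, profile=prof)

        def band_power(trace, lo, hi):
            sp = np.abs(np.fft.rfft(trace.Fx - trace.Fx.mean())) ** 2
            fr = np.fft.rfftfreq(trace.t.size, trace.t[1] - trace.t[0])
            return sp[(fr >= lo) & (fr <= hi)].sum()

        assert band_power(tr_v, 2800, 3200) > 50 * band_power(tr_c, 2800, 3200)

    def test_runout_alternating_peaks(self, material, cutter, process, no_vibration):
        """2 um runout: consecutive tooth passes carry different force peaks."""
        trace = om.simulate(material, cutter, no_vibration, process, 4)
        spr = int(round(process.rev_period / (trace.t[1] - trace.t[0])))
        half = spr // 2
        rev = trace.Fy[:spr]
        p1, p2 = np.abs(rev[:half]).max(), np.abs(rev[half:]).max()
        assert abs(p1 - p2) / max(p1, p2) > 0.05

    def test_trace_export_roundtrip(self, material, cutter, process, no_vibration, tmp_path):
        trace = om.simulate(material, cutter, no_vibration, process, 3)
        path = tmp_path / "trace.csv"
        trace.to_dataframe().to_csv(path, index=False)
        import pandas as pd

        df = pd.read_csv(path)
        assert df["Fx_N"].to_numpy() == pytest.approx(trace.Fx, abs=1e-12)
        assert trace.params["direction"] == 1
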