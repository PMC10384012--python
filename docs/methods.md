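# Methods

This note records the model `osteomill` implements, the numerical choices
behind it, and what its tests do and do not establish.

## Model summary

The simulator predicts cutting forces in slot micro-milling of cortical bone
with a helical two-flute flat-end cutter while the workpiece vibrates in X/Y
on a 2D platform. It is a *kinematic* mechanistic model: tool and workpiece
are rigid, trajectories are prescribed (no force–deflection coupling, no
regenerative chatter), and the force at any instant is the sum over engaged
cutting-edge micro-elements of shear and ploughing contributions weighted by
direction-dependent material coefficients.

Four stages:

1. **Trajectories.** Tip of tooth *j*: feed `v t` plus rotation
   `r (sin, cos)(ωt − 2πj/N)` plus spindle runout `r₀ (sin, cos)(ωt + ψ)`
   plus platform vibration `A sin(2πf t + φ)` per axis. The platform
   physically shakes the workpiece; the model folds that motion into the
   tool-relative-to-workpiece frame, which is an exact change of frame.
   The tooth-position angle θ = ωt − 2πj/N is zero on +Y, increases in the
   rotation direction, and a flute cuts the slot while θ mod 2π ∈ [0, π].
2. **Chip thickness.** Along the radial ray from the instantaneous tool
   centre through the tip, the governing machined surface is the *outer
   envelope* of the two candidate prior passes: the preceding tooth's pass
   (about one tooth period back) and the same tooth's previous revolution.
   Crossing times solve a collinearity equation; the thickness is
   `h = r − max L` over all admissible crossings (L = distance from centre to
   crossing, on the positive ray side), clipped at zero. A sample is tagged
   chip / empty-cut × same-tooth / different-tooth, or not-engaged.
3. **Coefficients.** Armarego oblique-cutting shear coefficients per cutting
   direction (chip-flow angle = helix angle; Merchant-type shear angle
   φ = π/4 − (β − γₙ)/2), and slip-line ploughing with slip-line angle
   η = ½ arccos μ, ploughed length l = rₑ sin η, and an equivalent rake angle
   γₑ(h) for the blunt edge. Ploughing coefficients are stored as nonnegative
   magnitudes; direction of action is applied once in the force rotation.
4. **Integration.** The flute over the axial depth H is cut into `n_slices`
   slices of height dz; slice k lags the flute bottom by θ_z = tan λ z_k / r
   and sees the tip thickness profile evaluated at its lagged angle (a time
   shift of θ_z/ω — the model treats h as a function of tooth angle, so the
   engagement windows of the entry/continuous/exit zones emerge from the
   profile itself). Engaged slices with h > 0 contribute
   dF_t = K_tc h dz + K_tp dz, dF_r = K_rc h dz + K_rp dz, dF_a = K_ac h dz,
   rotated by θ into Fx/Fy/Fz. Separated slices (h = 0) contribute nothing,
   including no ploughing: separation removes the rubbing contact, which is
   the mechanism by which vibration lowers mean force in this model.

## Parameters and defaults

| parameter | default | unit | meaning |
|---|---|---|---|
| τ₁, τ₂, τ₃ | 81.03, 94.48, 180.12 | MPa | shear strength, parallel/cross/vertical to osteons (bovine femur, double-shear tests) |
| μ₁, μ₂, μ₃ | 0.82, 0.98, 0.85 | – | rake-face friction coefficient per direction |
| d (= 2r) | 800 | µm | cutter diameter |
| γₙ / αₙ / λ | 5 / 10 / 35 | deg | rake / clearance / helix angle |
| rₑ | 5 | µm | edge (blunt-circle) radius |
| r₀, ψ | 2, 0 | µm, rad | spindle runout magnitude and phase (phase unreported; 0 by choice, configurable) |
| n | 3000 | rev/min | spindle speed |
| f_z | 10 | µm/tooth | feed per tooth (v = f_z N n/60 = 1000 µm/s) |
| H | 100 | µm | axial depth of cut |
| A, f | 0–3, 0–4000 | µm, Hz | vibration amplitude/frequency per axis (equal X/Y in the study grid) |
| phases | sin–cos | – | X at phase 0, Y a quarter period ahead (cos = sin(·+π/2)); "sin–sin" = both in phase |
| n_slices | 20 | – | axial slices (doubling changes RMS < 0.5%) |
| low-pass | 120 (order 4) | Hz | zero-phase Butterworth on force channels |

Internally everything is SI (Pa, m, rad, s); configuration surfaces accept
the boundary units above and convert once. Cutting direction uses the 1/2/3
coding with string aliases.

## Numerical choices

* **Time grid.** dt = 1/(K·f_max), K = 50, with f_max the fastest of the two
  vibration frequencies and the tooth-passing frequency, rounded so each
  revolution holds an integer number of steps (whole-revolution RMS windows).
  At 3 kHz this gives dt ≈ 6.7 µs, ~50 samples per vibration cycle.
* **Root finding.** Each candidate window (previous tooth:
  [t − T_tooth − δ, t); same tooth: [t − T_rev − δ, t − T_tooth]; margin
  δ = 0.25 T_tooth) is scanned at 200 uniform points for sign changes of the
  collinearity residual; every bracket is refined by 60 bisection steps
  (localising the root far below 1e-12 s). Single-start iteration is
  deliberately avoided: with vibration the residual has several roots per
  window and a naive solver can land on the wrong branch. Among all valid
  roots the largest centre distance governs (outer envelope). The scalar API
  `solve_previous_time` uses Brent refinement and returns the root giving the
  smallest nonnegative thickness, or `None` (→ empty cut).
* **Start-up.** Trajectories are evaluated at negative times as well, so the
  first revolution meets a well-defined virtual prior surface; revolution 1
  is discarded from every steady-state output regardless. Simulations in the
  shipped tests and scripts use 3–12 revolutions: 3–4 for force traces and
  sweeps (one discarded, RMS over the rest), 12 for the per-revolution
  material-conservation statistics.
* **Degenerate inputs.** f_z = 0 with no vibration/runout yields h ≡ 0;
  μ = 1 or μ = 0 collapse the ploughing force exactly; samples landing
  exactly on the θ = π engagement boundary are classified by a `<=` test and
  may fall either side at floating-point resolution (the adjacent sample
  carries ~0.01 f_z, so force traces are unaffected beyond one grid point).
* **Known closed-form checks.** Without vibration and runout the resolved
  thickness equals the classical f_z sin θ up to the trochoid correction
  (f_z²/r)[cos²θ/2 − sinθ cosθ/π] + O(f_z³/r²), ≈ 1.3% of f_z at worst for
  f_z/r = 1/40 — the solver reproduces this analytic deviation to ~0.1% of
  f_z, and matches an independent dense-sampling oracle to machine precision.
  Removed area per steady revolution equals N f_z · 2r within 2% (the ~1%
  positive bias of the radial-ray area integral is the Jacobian error of
  approximating the swept-area element by r dθ, not a solver defect).

## Design choices where the model was open

* **Oblique-coefficient denominator.** The compact typeset form of the shear
  coefficients omits the radical; the published oblique model carries
  √(cos²(φ+β−γₙ) + tan²η_c sin²β). The square root is the default
  (`armarego_sqrt=False` runs the literal compact reading).
* **Slip-line length.** `l = rₑ sin η` (product). The quotient reading
  `rₑ/sin η` is selectable (`slipline_length="quotient"`) and scales
  ploughing by 1/sin²η ≈ 11× at μ = 0.82 — documented because the compact
  notation admits both.
* **Ploughing sign.** γₑ < 0 for h < rₑ(1+sin γₙ) would make a literal
  tangential ploughing term negative; coefficients are stored as magnitudes
  (|sin γₑ|, cos γₑ) and the force rotation applies the sense once.
  Consequently K_rp ≥ K_tp only for h ≳ 0.29 rₑ (where |γₑ| ≤ π/4); at very
  small h the tangential ploughing magnitude dominates.
* **Axial ploughing.** No closed form exists for K_ap in this model; it
  defaults to zero (`kap` hook provided). The analysis focuses on in-plane
  forces, where ploughing is fully specified.
* **Governing surface.** Where both candidate surfaces give a nonnegative
  thickness the smaller governs; if the outer envelope lies beyond the tip
  radius the cut is empty even if the *other* candidate would suggest a chip.
  This follows from "material survives only outside every prior pass".
* **Sign conventions.** The force rotation is implemented literally
  (dFx = +dF_t cosθ + dF_r sinθ; dFy = −dF_t sinθ + dF_r cosθ; dFz = −dF_a);
  a `flip_y` switch exists because dynamometer axes may oppose the model
  frame.

## The synthetic "experiment" generator

`synth_experimental_trace` resamples a model trace to a dynamometer-like rate
(default 10 kHz) and adds seeded white Gaussian noise. It exists so the
model-vs-experiment comparison pipeline (resampling, zero-phase filtering,
RMS, percent error) is exercised end-to-end offline and deterministically.
It emulates sensor noise only — not the things that make real bone-milling
records deviate from the model: tissue heterogeneity (osteon vs interstitial
strength), brittle-fracture force fluctuations, machine-structure dynamics,
or sensor drift. A passing comparison against synthetic data therefore
validates the *pipeline*, not the model's absolute accuracy against hardware
measurements.

## Limitations

* Kinematic only: no regenerative dynamics, no tool deflection or wear, no
  temperature coupling, no Z-axis vibration, no bottom-edge geometry.
* Homogeneous material per direction: fracture, chip morphology and crack
  propagation are outside the model; measured forces fluctuate more than
  simulated ones.
* The amplitude trend of the filtered RMS force is monotone decreasing over
  the 0–3 µm grid in this model; the dip-then-rise reported from hardware
  experiments (impact-induced thickening at large amplitude) involves
  mechanisms the kinematic model does not contain. The frequency trend
  (non-increasing) is reproduced.
* Chip thickness history considers exactly the two prior passes the
  four-case analysis enumerates; with positive feed these bound the envelope,
  but zero-feed long-dwell scenarios would need deeper history.
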