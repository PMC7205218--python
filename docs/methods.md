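# Methods

This note records what the package models, the assumptions and parameters
behind each stage, what the synthetic data generator does and does not
emulate, and the numerical and design decisions that shaped the
implementation. Nothing here asserts an empirical result; all numbers quoted
as *defaults* are inputs, and all output quantities are computed by the test
suite or by `scripts/acceptance.py`.

## 1. Problem and modeling approach

A foot orthosis (FO) deforms under plantar load during walking, but its
plantar surface is hidden inside the shoe and cannot be tracked directly.
The package predicts the positions of a dense set of virtual plantar-surface
points from the orientations of six three-marker clusters ("triads") glued
around the FO contour, which *can* be tracked. The mapping from triad
orientations to surface-point positions is learned per FO in a dedicated
training session in which the surface is visible and loaded point-wise with
an instrumented stick; the learned surrogate is then applied frame-by-frame
to walking trials where only the triads are observed.

The chain of assumptions:

1. **Local observability.** Surface deformation changes the local surface
   normal under each triad, hence the triad's orientation. Six triads
   distributed around the contour (MedF, MedM, MedB, Back, LatB, LatF)
   sample the deformation state densely enough that a static,
   frame-independent regression from the 15 orientation features to the 165
   surface coordinates exists. There is no temporal model: each frame is
   predicted independently.
2. **Rigid-motion invariance of the features.** All orientations are
   expressed relative to the Back triad and referenced to the static trial
   (the feature is the Cardan vector of
   `R_rel,static^T · R_rel,current`), so a rigid motion of the whole FO
   changes no feature. The target positions are expressed in a session-local
   frame built from three FO markers, so they are also rigid-invariant.
   This is what lets a surrogate trained in a bench session transfer to
   walking, where the FO translates and rotates through the lab.
3. **Coverage.** The surrogate interpolates; it is only trusted where the
   training session bracketed the walking session. Two explicit coverage
   checks (triad vertical-displacement ranges, regional peak loads) report
   this rather than assuming it.

## 2. Kinematics

* **Triad frames.** A triad's frame takes marker 1 as origin,
  x̂ = unit(p₂ − p₁), ẑ = unit(x̂ × (p₃ − p₁)), ŷ = ẑ × x̂. Degenerate
  (collinear or coincident) marker sets raise `DegenerateGeometryError`
  rather than returning a garbage frame.
* **Cardan YXZ angles.** Rotations are decomposed as R = Ry·Rx·Rz with
  θx = arcsin(−R[1,2]) on the principal branch |θx| ≤ π/2. At gimbal lock
  (|cos θx| ≈ 0) only θy ± θz is determined; the convention θz = 0 is
  applied and the result flagged. Angles are a *parameterization* for the
  regression features, so the branch convention matters only for
  continuity, not correctness; the round-trip identity is exact to 1e-9
  away from lock (verified in the acceptance tests).
* **Session-local frame.** Default markers `(Back_1, MedF_1, LatF_1)` — the
  widest available triangle on the FO (see §7, "frame-marker choice").
* **Gap handling.** Marker gaps up to 10 frames are linearly interpolated;
  frames with longer gaps are dropped with a warning. Linear interpolation
  is adequate at 100 Hz for sub-10-frame gaps and introduces no ringing.
* **Filtering.** A zero-lag (forward-backward) 4th-order Butterworth
  low-pass, default cutoff 8 Hz at 100 Hz sampling, is available and applied
  by the pipeline to both sessions. 8 Hz retains the walking-deformation
  bandwidth (stance lasts ≥ 0.2 s, so the deformation signal lives well
  below 8 Hz) while suppressing the white marker noise; filtering is *off*
  by default in `build_dataset` so that noise-free algebraic identities hold
  on raw data.

## 3. Synthetic data generator

The generator exists so the whole method can be exercised and validated
end-to-end with a known ground truth. It emulates:

* **Geometry.** 55 surface points on an 11 × 5 foot-shaped grid
  (length 200 mm, half-width up to 45 mm), six contour triads with 20 mm
  marker branches, and the ten-region footprint partition used for
  stratification and coverage bookkeeping.
* **Deformation physics (phenomenological).** A point load F at footprint
  position p depresses the surface by a Gaussian kernel
  w(x) = −(F/k)·exp(−d²/2σ²) with stiffness k (N/mm) and spatial scale
  σ = 25 mm; heel-cup points within 45 mm of the heel center are clamped
  (the heel cup is the stiffest, most supported part of a real FO). Triads
  ride on the surface: each triad is tilted by the rotation carrying the
  vertical onto the local surface normal (from the kernel's analytic
  gradient), so triad orientation genuinely encodes nearby deformation —
  the same physical coupling the method relies on.
* **Training session.** Stick loads drawn uniformly over the footprint area
  until every region holds its quota (default 8 events/region), each a
  30-frame half-sine force ramp with 5 unloaded gap frames; stick-tip
  markers included; isotropic Gaussian marker noise (default 0.1 mm SD, a
  typical optical-mocap figure).
* **Walking session.** Ten steps at 100 frames/cycle, stance fraction 0.6;
  the load point travels heel-to-toe with a medial-lateral sway while the
  force follows a half-sine with a small (8 % of peak) plateau at the
  stance edges so event detection is exact; whole-FO sinusoidal rigid
  motion (default 10 mm / 5°) and marker noise are superimposed; the
  surface markers are *hidden* from the analysis, exactly as in a shoe.

It does **not** emulate: real FO constitutive behavior (no FEM, no
viscoelasticity, no load-history dependence), distributed plantar pressure
(loads are single points), marker occlusion or soft-tissue artifact,
double-support overlap between feet, or pressure-insole measurement noise.
The generator's role is to make the *method's* failure modes observable
(noise amplification, coverage gaps, rigid/non-rigid confounding), not to
reproduce any particular orthosis.

Default stiffnesses: 5 N/mm ("sport", compliant) and 12 N/mm ("regular",
stiff) — a > 2× contrast so condition discrimination is a fair end-to-end
check.

## 4. Dataset construction

* Load-cell calibration by ordinary linear regression of known force on raw
  signal (`scipy.stats.linregress`), with fit diagnostics returned.
* Frames with calibrated stick force < 0.1 N are discarded: unloaded frames
  carry no deformation signal and would dominate the loss with
  near-duplicate rows.
* Features: 15 numbers/frame — YXZ Cardan angles of the five non-Back
  triads relative to the Back triad, referenced to the static trial so the
  static pose maps to the zero vector (a well-conditioned origin for the
  network's normalized inputs).
* Targets: 165 numbers/frame — the 55 surface points in the session-local
  frame.
* Split: stratified 85 / 15 learning/test by loaded region, via
  shuffled round(0.85·n) per region, so every region appears in both halves;
  regions with fewer than 2 loaded frames fall back to learning-only with a
  warning.

## 5. Surrogate model

A fully connected feed-forward network (ReLU hidden layers, linear
165-unit output), implemented directly in NumPy (see §7). Inputs and
targets are z-score normalized by statistics **of the learning set only**
(a leakage guard, tested by corrupting test targets and asserting bitwise
identical weights).

* Hyperparameter grid: layers {1..5} × optimizer {adam, adadelta, adagrad}
  × learning rate {0.01, 0.005} × batch {16, 32, 64, 128} × epochs
  {20, 50, 100} = 360 configurations, scored by 5-fold cross-validation
  stratified on loaded region.
* Selected configuration (`FINAL_CONFIG`): 3 layers (2 hidden of width 64),
  Adam, learning rate 0.005, batch 16, 100 epochs.
* Determinism: weight init and batch shuffling derive from the config
  seed; identical data + config gives bitwise identical models.

## 6. Deformation analysis and statistics

* **Rigid/non-rigid separation.** Per frame, the optimal rigid
  rototranslation from the static surface onto the predicted surface is
  found by the SVD/polar-decomposition (Kabsch) solution with determinant
  correction; the residual after removing it is the non-rigid deformation.
  Depression/reformation is its vertical component, d = y − y_static
  (negative = pressed down).
* **Stance handling.** Stance is detected where load exceeds 5 % of the
  trial peak for at least 0.2 s (shorter excursions are discarded with a
  warning); each stance is linearly resampled to 101 samples (0–100 %
  stance); the subject's field is the cell-wise mean over cycles, giving a
  (55 points × 101 samples) deformation field.
* **Ground-truth fields.** The simulator's clean deformed surface is pushed
  through the *same* rigid-removal and stance-normalization pipeline, so a
  prediction-vs-truth comparison measures prediction error only, not the
  (shared) rigid-fit projection inherent in the deformation definition.
* **SPM comparison.** Paired t per cell across subjects (sport − regular);
  the family-wise critical value is the (1 − α) ceil-order-statistic
  quantile of the sign-flip permutation distribution of the field-wide
  max |t|. All 2ⁿ flips are enumerated when 2ⁿ ≤ 10,000 (exhaustive and
  seed-free); otherwise 10,000 random flips including the identity.
  Supra-threshold cells are clustered with face connectivity on the
  (11 × 5 surface grid) × 101-sample lattice, positive and negative
  excursions separately.

## 7. Numerical choices and design decisions

* **Hand-rolled network.** The grid requires Adadelta and Adagrad, which
  scikit-learn's MLP does not provide, and no deep-learning framework is a
  dependency; a dense NumPy implementation (a few hundred lines, fully
  deterministic, trivially serializable) was the smallest correct tool.
* **Tail averaging.** The trained weights are the average of the last 20
  per-epoch snapshots. At the fixed small-batch settings Adam reaches a
  stochastic-gradient plateau whose bounce dominates the fit error
  (noise-free loss observed oscillating between ~0.002 and ~0.009 late in
  training); averaging the tail de-noises the plateau without touching
  optimizer, learning rate, epochs or batch size.
* **Gradient clipping.** Global gradient-norm clipping at 1.0 on every
  step removes occasional late-training loss spikes under small batches.
* **Frame-marker choice.** The session-local frame uses
  `(Back_1, MedF_1, LatF_1)` rather than three posterior markers: with
  short (~67 mm) baselines, noise- and deformation-driven rotation of the
  frame is amplified by up to ~195 mm of lever arm at the forefoot targets
  and dominates the error floor; the widest triangle minimizes it. The
  marker choice is a `build_dataset` argument, so any convention can be
  used.
* **Divide-by-zero conventions.** Paired t at zero variance: 0/0 ≡ 0,
  x/0 ≡ ±∞ (so constant nonzero differences are always supra-threshold);
  NRMSE at (numerically) zero maximal deformation is NaN with the marker
  indices reported — these are typically the clamped heel-cup points.
* **Permutation efficiency.** |t| is invariant under a global sign flip, so
  only 2ⁿ⁻¹ representatives (first subject fixed at +1) are enumerated; and
  with q = mean²/mean-square, t² = (n−1)q/(1−q) is monotone in q, so the
  field-wide max |t| is recovered from the max of q with one matrix product
  per batch of permutations. Both identities are exact (regression-tested
  against the brute-force implementation).
* **Seeding.** Every derived seed comes from
  `np.random.SeedSequence(seed).generate_state(n) mod 2³¹`, so one integer
  reproduces the whole study bitwise.
* **File formats.** TRC (text) for trajectories, CSV for tables, a zip of
  `.npz` + JSON for models, JSON for configuration. C3D reading is
  available only if the optional `ezc3d` package is installed.

## 8. Limitations

* The surrogate is per-FO and per-marker-placement: retraining is required
  whenever triads are re-glued or the orthosis changes.
* Frame-independent regression cannot represent viscoelastic or
  load-history effects; the generator is elastic, so this limitation is
  untested here.
* Accuracy is only expected inside the training envelope; the coverage
  checks report violations but nothing corrects for them.
* The Gaussian-kernel generator is phenomenological. Conclusions about the
  *method* (noise floors, coverage sensitivity, statistical calibration)
  transfer; conclusions about any particular orthosis material do not.
* The 101-sample stance normalization assumes stance phases are
  time-warpable to a common cycle; pathological gaits with qualitatively
  different load curves would blur the mean field.
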