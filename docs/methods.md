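# Methods

This note documents the model behind `gaitwrench`, the numerical choices
made where the mathematics as usually written is ambiguous or degenerate,
what the synthetic data does and does not emulate, and the package's known
limitations. It states no empirical result that the test suite or
`scripts/acceptance.py` does not itself compute.

## Model and assumptions

**Rigid multibody, revolute joints.** The body is a tree of rigid segments
rooted at a floating base. Multi-DOF joints are ordered revolute sequences
composing intrinsically (each axis rotates with the preceding DOFs of the
same joint); the bundled hip is flexion/extension then ab/adduction. World
frame: right-handed, Z up, ground plane z = 0, gravity (0, 0, −9.81) m/s².

**Contact model.** Each foot is a heel–toe line segment; its distributed
contact reduces to a single force at the center of pressure (COP) on that
segment. Three moment components per foot are therefore neglected: the two
sole-plane components (eliminated by working at the COP) and the
sole-normal free moment produced by tangential friction during turning. The
6-point sole contour is used only to bound the COP and classify support. Foot
width, compliant contact, and flight phases are out of scope.

**D'Alembert aggregation.** Per segment, the "inertia force" includes
gravity, F_i = m_i (g − a_i), and the inertia couple is
τ_i = −(I_i ω̇_i + ω_i × I_i ω_i) with I_i the world-frame tensor about the
segment com. The Euler term ω × Iω is included even though elementary
presentations of the resultant-couple sum sometimes omit it; without it the
aggregate is not the true dynamic wrench. The aggregate about O0 (the
origin-segment frame origin, re-expressed in world coordinates every sample)
is reduced by the standard Poinsot decomposition: couple
T = ((F·M)/|F|²) F, axis offset p = (F × M)/|F|². A cross-product form of
the couple that appears in some write-ups does not produce a collinear
couple and is not equipollence-preserving; the dot-product projection is
the only reduction consistent with both requirements, and equipollence (the
moment about arbitrary probe points) is the tested contract.

**Support classification.** The central axis pierces z = 0 at the
"subpoint". Point-in-polygon is boundary-inclusive with a 1 mm tolerance
band, because misclassification at phase transitions is the method's
dominant failure mode and a pierce point grazing a contour edge should not
flip the phase. Classification is stateless per sample (no hysteresis) and
depends only on the force direction, not its magnitude. A pierce point
inside neither contour is treated as double support; if it is additionally
not between the feet the sample is flagged with a diagnostic warning rather
than rejected, so trajectories remain processable.

**COP coupling and the DDCS.** Writing M = A + a·û(AB), N = C + b·û(CD),
coplanarity of the central axis with M and N gives the closed form

    b(a) = −[(PM × F)·PC] |CD| / [(PM × F)·CD],

degenerate only when CD is parallel to the plane of PM and F (reported as an
error; the optimizer skips such grid points). The DDCS origin O is computed
as the closest point on line MN to the central axis with a consistency gap
check (< 1e−8 m) — algebraically equivalent to the textbook intersection
formula where that formula is well-defined, and robust where it is not.
Axes: X = û(OM), Y = û(OM × OP), Z = X × Y. The lever arm r is stored
signed (N − O = −r X), so the 5×5 system remains valid if O falls outside
segment MN; the singularity guard is |l + r| ≤ 1e−9 m (coincident COPs).
After transforming the required contact wrench to the DDCS, the X-moment
about O cannot be produced by pure forces on the X-axis; it is dropped and
logged per sample (`dropped_MXD`) as a model-error diagnostic. This is the
only reading that makes the retained system square.

**Energy objective.** E = Σᵢ fᵢ Tᵢ², with per-joint-class weights
interpreted as inverse elastic joint stiffnesses (f = 1/(2K)); only weight
ratios matter (scaling all weights rescales E but moves no argmin), which is
why the hip flexion/extension weight is pinned at 1. Defaults
[q0, q1, q2] = [1.0, 2.1, 0.1] (hip ab/adduction, knee, ankle) are the
shipped calibrated walking values; they are overridable everywhere.

## Optimizer

For fixed kinematics the joint-moment vector is affine in the contact
forces (contacts enter the Newton–Euler backward pass linearly), hence
affine in k at fixed a, hence E is an exact convex quadratic in k. The
implementation obtains the per-joint affine coefficients by evaluating the
full inverse-dynamics path at k = 0 and k = 1 — exact 2-point interpolation
of an affine map, robust to any inverse-dynamics internals — and assembles
e₀, e₁, e₂ by per-class aggregation. k* = −e₁/(2e₀) is closed-form; a is
traversed on a grid (default l_f/200, sub-millimetre for a typical foot)
over the feasible set {0 ≤ a ≤ l_f, 0 ≤ b(a) ≤ l_f}. Grid traversal is the
method: it cannot fall into a local minimum of the (generally
non-polynomial) E(a) profile. E is quadratic in k but *not* polynomial in
a — l, r and the frame rotation depend nonlinearly on a — so no closed form
over a is attempted.

Deterministic tie-breaking: ties in E within 1e−9 relative resolve toward
smaller a, then smaller |k − ½|. Grid points with e₀ ≤ 1e−12 (flat or
numerically concave k-direction, e.g. vanishing axial force) are skipped
with a diagnostic; if every point is skipped the sample is flagged as an
estimation failure. k is unconstrained by default — the closed-form
minimiser assumes an unconstrained quadratic, and near weight transfer the
energy-minimal split can leave [0, 1] when the axial force is small; a
clamp option exists for friction-plausible output.

Single-support samples bypass the optimizer entirely: the solution is
closed-form and exact by force balance.

**Calibration.** Only double-support samples inform the weights (single
support is closed-form), so calibration scores the mean squared error of
the six world-frame force components over double-support samples and
traverses (q1, q2) on (0, 5] at 0.1 (2500 combinations), q0 fixed at 1 by
default. The expensive per-sample, per-a geometry and the affine
joint-moment coefficients are factor-independent and precomputed once;
estimation and calibration share this one numeric path, so calibrating
against the estimator's own output recovers planted factors with objective
exactly zero. Ties break toward smaller q1, then q2.

## Synthetic data

`generate_model(height, mass)` builds a 12-segment model (pelvis, torso with
head, welded arms, 2 × thigh/shank/foot; 8 actuated DOFs) from Winter-style
segment mass and length fractions (constants in `synthetic_gait.py`); limb
inertias are slender-rod, trunk/feet box approximations. Total mass is
conserved exactly.

`generate_gait` is task-space: foot placements, stance/swing windows, and a
designed trajectory for the ground pierce point of the inertial wrench — a
heel-to-toe COP roll under each stance foot, crossing the inter-foot gap
during weight transfer, sized so the *classified* double-support fraction
matches the requested parameter. The pelvis trajectory realising that
pierce path cannot be written open-loop (at walking frequency the pierce
point responds to a pelvis harmonic of index k amplified in phase by
1 + z(kω)²/g), so it is found by a safeguarded fixed-point iteration:
evaluate the true pierce point through the package's own wrench pipeline,
correct the pelvis harmonics with the inverted-pendulum transfer as a
Newton preconditioner, cap each step at 4 cm (large steps leave the
linear-response regime by driving the legs toward the straight-knee reach
limit — the pelvis height deliberately keeps ~7% knee-flexion slack), keep
the best iterate, and halve the step on regression. Joint angles follow by
per-leg 3-DOF inverse kinematics, and every channel is refit as a truncated
Fourier series (24 harmonics), so published trajectories are exactly
periodic with analytic, mutually consistent velocities and accelerations;
stance feet sit on the ground to within the truncation residual (a few mm).
The seed jitters the cycle period (cadence noise) and starting phase.

These kinematics are exercise-grade, not biofidelic: no muscle dynamics, no
arm swing, no trunk rotation, simplified inertias. Passing tests demonstrate
the estimator's internal consistency and recovery properties on
balance-consistent walking-like motion — not accuracy on measured human
data.

`generate_truth` emits reference contact forces that satisfy the same
retained balance equations as the estimator output. Mode `arbitrary` plants
smooth a(t), k(t) profiles inside the feasible region and solves for the
forces (balance holds by construction). Mode `energy_minimal` locates
(a, k) by exhaustive direct grid search of the energy surface — nested
zoomed dense-k scans at 2e−4 resolution, no closed-form minimisation — so
optimizer-recovery tests compare against an independent search. Samples with
no feasible COP pairing are flagged and excluded rather than fabricated.

## Numerical choices and degenerate inputs

- Numeric rank uses the standard singular-value tolerance
  (max dim · eps · σ_max), so the rank results are reproducible bit-for-bit.
- Central-axis reduction requires |F| > 1e−9 N; below that the wrench is a
  pure couple with no axis (free-fall-like states) and an error is raised.
- A pierce point requires |F_z| > 1e−9 N (axis not parallel to the ground).
- b(a) denominators below 1e−12 (on unit-force scale), frame constructions
  with |OM| < 1e−9 m or P on the X-axis, and COP-line/axis gaps ≥ 1e−8 m
  are reported as degenerate-geometry errors; the traversal records and
  skips them.
- Missing motion-table derivatives are filled by Savitzky–Golay smoothing
  differentiation (window 7, order 3, configurable), exact for polynomial
  trajectories up to the filter order including at the edges; non-uniform
  time grids fall back to `np.gradient`.
- CSV floats are written with shortest-round-trip repr and parsed with
  correctly-rounded conversion, so write → read is lossless and repeated
  runs are byte-identical.

## Problem sizes used in the test suite

The suite runs entirely on synthetic data chosen at desk scale: one gait
cycle per seed (~116 samples at 10 ms), five seeds for recovery statistics,
100 double-support frames for oracle-equivalence and conservation checks,
and the full 2500-combination calibration grid on one trajectory. The
calibration stochastic-recovery property is exercised on five seeded
trajectory sets in the unit suite.

## Known limitations

- The sole-normal free moment and foot-width (2-D COP) effects are not
  estimated; `dropped_MXD` quantifies the residual the pure-force model
  cannot carry.
- Phase misclassification near transitions propagates into force error;
  the 1 mm contour tolerance mitigates but does not remove it.
- The minimum-energy hypothesis is an assumption about preferred motor
  behaviour: deliberate COP shifts without postural change (lateral weight
  shifting while standing) violate it and are not recoverable.
- The unconstrained k* can imply axial force splits outside [0, 1] near
  weight transfer; the clamp option trades energy optimality for
  plausibility.
- Joint weight factors are assumed constant per joint class across the
  gait; no stiffness modulation within the cycle.
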