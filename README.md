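# gaitwrench

Sensor-free estimation of the ground **contact forces and moments (CFMs)**
under each foot of a walking human or human–exoskeleton system, from
whole-body kinematics alone — no force plates, no instrumented insoles.

Exoskeleton controllers need per-foot ground reaction forces to compute joint
moments by inverse dynamics, but wearable force sensing is fragile and
expensive. The obstacle to computing the forces instead is static
indeterminacy: in double support there are 12 unknown contact components (6
forces + 6 moments) against 6 balance equations, and the coefficient matrix
of the force-only system has rank 5 in *any* ordinary coordinate frame — the
transverse force pair sharing a line of action is unresolvable.

`gaitwrench` implements a decomposition that makes the problem tractable:

1. **D'Alembert aggregation.** All segment gravity + inertia loads are summed
   into one wrench about a body reference point `O0`, then reduced to its
   central (screw) axis: a force **F** plus a collinear couple.
2. **Support detection.** Where the central axis pierces the ground
   determines the phase. Inside one foot's sole contour, the pierce point
   *is* that foot's center of pressure (COP) and the solution is closed-form
   and exact: that foot carries −**F**, the other nothing.
3. **COP coupling.** In double support, each foot's contact reduces to a pure
   force at its COP (`M` on the left heel–toe segment at distance `a` from
   the heel, `N` on the right at distance `b`). Balance forces the central
   axis to be coplanar with `M` and `N`, so `b` is a closed-form function of
   `a`: one scalar locates both COPs.
4. **Dynamic decoupled coordinate system (DDCS).** A per-sample frame with
   origin `O` at the axis ∩ COP-line intersection and X-axis along the
   COP–COP line. There the balance system becomes square and full-rank:
   `FX`, `FLY`, `FLZ`, `FRY`, `FRZ` solve a 5×5 system with lever arms
   `l = |OM|`, `r = |ON|`; only the axial split `FLX = k·FX`,
   `FRX = (1−k)·FX` remains free. Twelve unknowns → two: `(a, k)`.
5. **Minimum energy hypothesis.** The body is assumed to realise the contact
   distribution minimising the stiffness-weighted squared joint moments
   `E = Σᵢ fᵢ Tᵢ²` (weights per joint class: hip flexion/extension 1, hip
   ab/adduction `q0`, knee `q1`, ankle `q2`; default `[1.0, 2.1, 0.1]`). For
   fixed `a`, `E` is an exact convex quadratic in `k` with closed-form
   minimiser `k* = −e₁/2e₀`; `a` is resolved by traversing its feasible grid
   (`0 ≤ a ≤ l_f`, `0 ≤ b(a) ≤ l_f`), which cannot miss the global grid
   minimum.

A synthetic-gait module generates anthropometric body models, kinematically
consistent walking (with a pierce-point-tracking pelvis trajectory, so
single/double-support phases are realistic), and ground-truth contact
forces — every stage is testable without any external dataset.

## Worked example

```
$ gaitwrench synth --out-dir demo --seed 7 --dt 0.02
wrote model.yaml, motion.csv (58 samples), truth.csv to demo (seed=7)

$ gaitwrench estimate --model demo/model.yaml --motion demo/motion.csv --out demo/cfm.csv
INFO gaitwrench: estimated 58 samples (0 failed); |dropped X-moment| mean 9.7 N*m, max 32 N*m
wrote 58 rows to demo/cfm.csv
```

Three rows of `demo/cfm.csv` (1.75 m / 70 kg model, one gait cycle):

```
 time       phase     a     b      k         E     flz     frz  dropped_mxd
0.200      double 0.065 0.204  3.653  9761.457 358.868 377.600        0.001
0.500 left_single 0.139   NaN  1.000 25496.177 604.352   0.000       11.868
0.800      double 0.092 0.101 -2.268 13480.955 262.092 457.530        0.014
```

Reading the rows: at `t = 0.2 s` (weight transfer) both feet are loaded and
the vertical forces `flz + frz ≈ 736 N` exceed body weight because the body
is accelerating upward; the COPs sit `a = 6.5 cm` from the left heel and
`b = 20.4 cm` from the right heel (the trailing foot is on its toe). At
`t = 0.5 s` the left foot carries the entire resultant (604 N, mid-stance
unloading) exactly, with the right foot at zero. `E` is the weighted
joint-energy objective at the optimum; `dropped_mxd` logs the moment
component about the COP–COP axis that pure COP forces cannot produce — a
per-sample model-error diagnostic (zero when the wrench truly passes through
the COP line). The unconstrained split fraction `k` can leave `[0, 1]` near
transitions where the axial force is small; pass `--clamp-k` for
friction-plausible output.

Calibration of the joint weight factors against reference forces (force-plate
data, or the bundled synthetic truth):

```
$ gaitwrench calibrate --model demo/model.yaml --motion demo/motion.csv --reference demo/cfm.csv
best factors [q0, q1, q2] = [1, 2.1, 0.1]  (MSE = 0 N^2 over 14 samples)
```

`gaitwrench rank-check` prints the rank-deficiency table that motivates the
DDCS (rank 5 for every placement, rotated or axis-aligned).

## Layout

| module | role |
| --- | --- |
| `body_model` | segment tree, validation, forward kinematics (poses, velocities, accelerations) |
| `inertial_wrench` | D'Alembert aggregation and central-axis (Poinsot) reduction |
| `support_detector` | pierce-point phase classification; exact single-support solution |
| `ddcs_solver` | COP coupling `b(a)`, DDCS frame, 5×5 decoupled solve, rank utilities |
| `inverse_dynamics` | Newton–Euler backward pass; joint moments affine in contact forces |
| `energy_optimizer` | feasible `a` range, traversal + closed-form `k*`, trajectory driver |
| `calibration` | grid traversal of `(q1, q2)` against reference forces |
| `synthetic_gait` | anthropometric models, walking synthesis, ground-truth generation |
| `motion_io`, `cli` | CSV / `.mot` / `.sto` parsing, output tables, `gaitwrench` CLI |

See `docs/methods.md` for the model assumptions, numerical choices, and
known limitations.
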