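"""Minimum joint-energy resolution of the two remaining contact unknowns.

After the DDCS solve, a double-support sample has exactly two free scalars:
the left COP parameter ``a`` and the axial split fraction ``k``.  The method
assumes the body realises, among all balance-consistent contact
distributions, the one minimising a stiffness-weighted sum of squared joint
moments

    E = sum_i f_i T_i^2,

with per-joint-class weights f_i (hip flexion/extension = 1 as reference,
hip ab/adduction = q0, knee = q1, ankle = q2; each weight is 1/(2K_i) for an
elastic-joint stiffness K_i, so stiffer joints are cheaper).

For fixed ``a`` the joint moments are affine in ``k`` (contacts enter the
inverse dynamics linearly), so E is an exact convex quadratic
E = e0 k^2 + e1 k + e2 with closed-form minimiser k* = -e1/(2 e0).  The outer
variable ``a`` is resolved by traversing its feasible grid — deliberately no
gradient or local method, so the global grid minimum cannot be missed.

The per-joint affine coefficients are obtained by evaluating the full
inverse-dynamics path at k = 0 and k = 1 (exact 2-point interpolation of an
affine map) and the quadratic coefficients by per-class aggregation; the
calibration module reuses precomputed problems through the very same
routines, so calibrating against the estimator's own output is numerically
exact.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .body_model import BodyModel, MotionSample, SegmentKinematics, forward_kinematics
from .ddcs_solver import (ContactSolution, DDCSFrame, DegenerateGeometryError,
                          contact_geometry, ddcs_frame, solve_decoupled, split_axial)
from .inertial_wrench import (CentralAxisWrench, PureCoupleError, Wrench,
                              aggregate_inertial_wrench, central_axis_reduction)
from .inverse_dynamics import Contact, contact_jacobian, free_joint_moments, joint_moments
from .support_detector import (DOUBLE, NoPiercePointError, SupportState,
                               classify_support, single_support_solution)

__all__ = [
    "EnergyModel",
    "FeasibleRange",
    "EnergyProfile",
    "DoubleSupportProblem",
    "MissingFactorError",
    "NoFeasibleCopError",
    "EstimationError",
    "energy",
    "feasible_a_range",
    "build_problem",
    "solve_with_factors",
    "energy_profile",
    "optimize_sample",
    "estimate_trajectory",
    "DEFAULT_GRID_DIVISIONS",
]

#: default a-grid resolution: foot length / 200 (sub-millimetre for a typical foot)
DEFAULT_GRID_DIVISIONS = 200


class MissingFactorError(KeyError):
    """A DOF's joint class has no weight factor in the energy model."""


class NoFeasibleCopError(ValueError):
    """No COP pairing satisfies 0 <= a <= lf and 0 <= b(a) <= lf."""


class EstimationError(RuntimeError):
    """The sample admits no energy-minimal estimate (all grid points skipped)."""


@dataclass(frozen=True)
class EnergyModel:
    """Per-joint-class weight factors of the energy objective."""

    factors: dict

    @classmethod
    def from_q(cls, q0: float = 1.0, q1: float = 2.1, q2: float = 0.1) -> "EnergyModel":
        """Weights keyed by joint class; defaults are the calibrated walking values."""
        if min(q0, q1, q2) <= 0:
            raise ValueError("all weight factors must be > 0")
        return cls(factors={"hip_fe": 1.0, "hip_aa": q0, "knee": q1, "ankle": q2})

    @classmethod
    def default(cls) -> "EnergyModel":
        return cls.from_q()

    def factor_vector(self, joint_classes) -> np.ndarray:
        try:
            return np.array([self.factors[c] for c in joint_classes], dtype=float)
        except KeyError as e:
            raise MissingFactorError(f"no weight factor for joint class {e.args[0]!r}") from e


def energy(T, em: EnergyModel) -> float:
    """Weighted joint energy E = sum_i f_i T_i^2 for a JointMomentResult."""
    f = em.factor_vector(T.joint_classes)
    return float(f @ (T.moments * T.moments))


# ---------------------------------------------------------------------------
# feasible COP range
# ---------------------------------------------------------------------------

@dataclass
class FeasibleRange:
    a_grid: np.ndarray
    b_grid: np.ndarray  # NaN where infeasible
    mask: np.ndarray  # boolean feasibility per grid point
    a1: float
    a2: float


def _a_grid(lf: float, grid_step: float) -> np.ndarray:
    n = max(int(round(lf / grid_step)), 1)
    return np.linspace(0.0, lf, n + 1)


def feasible_a_range(*, A, B, C, D, P, f_dir, grid_step: float) -> FeasibleRange:
    """Scan a over [0, lf_left] and keep the points with 0 <= b(a) <= lf_right."""
    from .ddcs_solver import coupled_b

    A, B, C, D = (np.asarray(x, float) for x in (A, B, C, D))
    lf_l = float(np.linalg.norm(B - A))
    lf_r = float(np.linalg.norm(D - C))
    a_grid = _a_grid(lf_l, grid_step)
    b_grid = np.full_like(a_grid, np.nan)
    mask = np.zeros(a_grid.shape, dtype=bool)
    for i, a in enumerate(a_grid):
        try:
            b = coupled_b(a, A=A, B=B, C=C, D=D, P=P, f_dir=f_dir)
        except DegenerateGeometryError:
            continue
        b_grid[i] = b
        mask[i] = 0.0 <= b <= lf_r
    if not mask.any():
        raise NoFeasibleCopError("no feasible COP pairing on the a-grid")
    feas = a_grid[mask]
    return FeasibleRange(a_grid=a_grid, b_grid=b_grid, mask=mask,
                         a1=float(feas[0]), a2=float(feas[-1]))


# ---------------------------------------------------------------------------
# double-support problem precomputation
# ---------------------------------------------------------------------------

@dataclass
class DoubleSupportProblem:
    """Everything about one double-support sample that does not depend on the
    energy-model factors: per-feasible-a geometry, decoupled forces, the
    affine joint-moment coefficients T(k) = u + k v, and their per-class
    quadratic aggregates."""

    t: float | None
    a: np.ndarray  # (na,) feasible grid values
    b: np.ndarray
    dropped_MXD: np.ndarray
    x: np.ndarray  # (na, 5) decoupled solutions [FX, FLY, FLZ, FRY, FRZ]
    fl0_w: np.ndarray  # (na, 3) world left force at k = 0
    fr0_w: np.ndarray
    g_w: np.ndarray  # (na, 3) d f_left / dk (world); d f_right / dk = -g_w
    M: np.ndarray  # (na, 3) left COPs
    N: np.ndarray
    frames: list[DDCSFrame]
    u: np.ndarray  # (na, n_dofs)
    v: np.ndarray
    class_names: list[str]
    Suu: np.ndarray  # (na, n_classes)
    Suv: np.ndarray
    Svv: np.ndarray
    feasible: FeasibleRange | None = None
    skipped: list[str] = field(default_factory=list)
    state: SupportState | None = None


def build_problem(model: BodyModel, kin: SegmentKinematics, w: Wrench,
                  caw: CentralAxisWrench, grid_step: float | None = None,
                  t: float | None = None, state: SupportState | None = None) -> DoubleSupportProblem:
    """Precompute the traversal grid for one double-support sample."""
    left, right = kin.feet["left"], kin.feet["right"]
    A, B, C, D = left.heel, left.toe, right.heel, right.toe
    P, f_dir = caw.point, caw.direction
    if grid_step is None:
        grid_step = float(np.linalg.norm(B - A)) / DEFAULT_GRID_DIVISIONS

    rng = feasible_a_range(A=A, B=B, C=C, D=D, P=P, f_dir=f_dir, grid_step=grid_step)
    T_free = free_joint_moments(model, kin)
    seg_l, seg_r = model.feet["left"].segment, model.feet["right"].segment

    rows = []
    skipped: list[str] = []
    for a in rng.a_grid[rng.mask]:
        try:
            geom = contact_geometry(a, A=A, B=B, C=C, D=D, P=P, f_dir=f_dir)
            frame = ddcs_frame(geom)
            sys = solve_decoupled(frame, w)
        except DegenerateGeometryError as e:
            skipped.append(f"a={a:.6g}: {e}")
            continue
        _, _, fl0_w, fr0_w = split_axial(sys, 0.0)
        g_w = sys.x[0] * frame.x_axis  # d f_left / dk in world frame
        J_l = contact_jacobian(model, kin, seg_l, geom.M)
        J_r = contact_jacobian(model, kin, seg_r, geom.N)
        u = T_free + J_l @ fl0_w + J_r @ fr0_w
        v = J_l @ g_w - J_r @ g_w
        rows.append((a, geom.b, sys.dropped_MXD, sys.x, fl0_w, fr0_w, g_w,
                     geom.M, geom.N, frame, u, v))
    if not rows:
        raise EstimationError("all feasible a-grid points degenerate; no estimate for this sample")

    a_arr = np.array([r[0] for r in rows])
    u_arr = np.array([r[10] for r in rows])
    v_arr = np.array([r[11] for r in rows])

    class_names = sorted(set(model.dof_classes))
    nc = len(class_names)
    Suu = np.zeros((len(rows), nc))
    Suv = np.zeros((len(rows), nc))
    Svv = np.zeros((len(rows), nc))
    for ci, cname in enumerate(class_names):
        idx = [j for j, c in enumerate(model.dof_classes) if c == cname]
        uu, vv = u_arr[:, idx], v_arr[:, idx]
        Suu[:, ci] = np.einsum("ij,ij->i", uu, uu)
        Suv[:, ci] = np.einsum("ij,ij->i", uu, vv)
        Svv[:, ci] = np.einsum("ij,ij->i", vv, vv)

    return DoubleSupportProblem(
        t=t,
        a=a_arr,
        b=np.array([r[1] for r in rows]),
        dropped_MXD=np.array([r[2] for r in rows]),
        x=np.array([r[3] for r in rows]),
        fl0_w=np.array([r[4] for r in rows]),
        fr0_w=np.array([r[5] for r in rows]),
        g_w=np.array([r[6] for r in rows]),
        M=np.array([r[7] for r in rows]),
        N=np.array([r[8] for r in rows]),
        frames=[r[9] for r in rows],
        u=u_arr, v=v_arr,
        class_names=class_names, Suu=Suu, Suv=Suv, Svv=Svv,
        feasible=rng, skipped=skipped, state=state,
    )


# ---------------------------------------------------------------------------
# inner (closed-form) and outer (traversal) minimisation
# ---------------------------------------------------------------------------

@dataclass
class EnergyProfile:
    """E(k) quadratic coefficients along the feasible a-grid."""

    a: np.ndarray
    e0: np.ndarray
    e1: np.ndarray
    e2: np.ndarray
    k_star: np.ndarray
    E_min: np.ndarray
    valid: np.ndarray  # e0 > tolerance (convex direction exists)


def energy_profile(problem: DoubleSupportProblem, em: EnergyModel,
                   e0_tol: float = 1e-12) -> EnergyProfile:
    f = em.factor_vector(problem.class_names)
    e0 = problem.Svv @ f
    e1 = 2.0 * (problem.Suv @ f)
    e2 = problem.Suu @ f
    valid = e0 > e0_tol
    k_star = np.full_like(e0, np.nan)
    E_min = np.full_like(e0, np.nan)
    k_star[valid] = -e1[valid] / (2.0 * e0[valid])
    E_min[valid] = e2[valid] - e1[valid] ** 2 / (4.0 * e0[valid])
    return EnergyProfile(a=problem.a, e0=e0, e1=e1, e2=e2,
                         k_star=k_star, E_min=E_min, valid=valid)


def solve_with_factors(problem: DoubleSupportProblem, em: EnergyModel,
                       clamp_k: bool = False, tie_tol: float = 1e-9) -> ContactSolution:
    """Traverse the feasible a-grid, minimise E(k) in closed form at each a,
    and return the globally minimal contact solution.

    Ties in E (within ``tie_tol`` relative) break toward smaller a, then
    smaller |k - 1/2|, so output is deterministic.
    """
    prof = energy_profile(problem, em)
    if not prof.valid.any():
        raise EstimationError("energy quadratic flat/concave at every feasible a")
    E = np.where(prof.valid, prof.E_min, np.inf)
    i0 = int(np.argmin(E))
    near = np.flatnonzero(E <= E[i0] + tie_tol * max(abs(E[i0]), 1e-30))
    if len(near) > 1:
        order = np.lexsort((np.abs(prof.k_star[near] - 0.5), problem.a[near]))
        i0 = int(near[order[0]])

    k = float(prof.k_star[i0])
    if clamp_k:
        k = min(max(k, 0.0), 1.0)
    fl = problem.fl0_w[i0] + k * problem.g_w[i0]
    fr = problem.fr0_w[i0] - k * problem.g_w[i0]
    FX, FLY, FLZ, FRY, FRZ = problem.x[i0]
    moments = problem.u[i0] + k * problem.v[i0]
    e0, e1, e2 = prof.e0[i0], prof.e1[i0], prof.e2[i0]
    warnings = tuple(problem.skipped[:1])
    if problem.state is not None and problem.state.warning:
        warnings = warnings + (problem.state.warning,)
    return ContactSolution(
        phase=DOUBLE,
        t=problem.t,
        a=float(problem.a[i0]),
        b=float(problem.b[i0]),
        k=k,
        f_left=fl,
        f_right=fr,
        f_left_ddcs=np.array([k * FX, FLY, FLZ]),
        f_right_ddcs=np.array([(1.0 - k) * FX, FRY, FRZ]),
        cop_left=problem.M[i0],
        cop_right=problem.N[i0],
        joint_moments=moments,
        energy=float(e0 * k * k + e1 * k + e2),
        dropped_MXD=float(problem.dropped_MXD[i0]),
        frame=problem.frames[i0],
        warnings=warnings,
    )


# ---------------------------------------------------------------------------
# per-sample and per-trajectory drivers
# ---------------------------------------------------------------------------

def optimize_sample(model: BodyModel, sample: MotionSample, em: EnergyModel | None = None,
                    grid_step: float | None = None, clamp_k: bool = False) -> ContactSolution:
    """Full estimate for one motion sample.

    Single-support samples short-circuit to the exact closed-form solution
    (the optimizer is never invoked); double-support samples run the grid
    traversal with closed-form inner minimisation.
    """
    em = em or EnergyModel.default()
    kin = forward_kinematics(model, sample)
    w = aggregate_inertial_wrench(model, kin)
    caw = central_axis_reduction(w)
    state = classify_support(caw, kin)
    if state.phase != DOUBLE:
        sol = single_support_solution(w, caw, state, kin)
        side = "left" if sol.cop_left is not None else "right"
        contact = Contact(model.feet[side].segment,
                          sol.f_left if side == "left" else sol.f_right,
                          sol.cop_left if side == "left" else sol.cop_right)
        T = joint_moments(model, kin, (contact,))
        sol.joint_moments = T.moments
        sol.energy = energy(T, em)
        sol.t = sample.t
        return sol
    problem = build_problem(model, kin, w, caw, grid_step=grid_step, t=sample.t, state=state)
    return solve_with_factors(problem, em, clamp_k=clamp_k)


def estimate_trajectory(model: BodyModel, samples, em: EnergyModel | None = None,
                        grid_step: float | None = None, clamp_k: bool = False) -> list[ContactSolution]:
    """Per-sample estimates for a motion table; failures are recorded as
    ``phase='failed'`` rows and processing continues."""
    em = em or EnergyModel.default()
    out: list[ContactSolution] = []
    for s in samples:
        try:
            out.append(optimize_sample(model, s, em, grid_step=grid_step, clamp_k=clamp_k))
        except (NoFeasibleCopError, EstimationError, DegenerateGeometryError,
                PureCoupleError, NoPiercePointError) as e:
            out.append(ContactSolution(phase="failed", t=s.t, warnings=(str(e),)))
    return out
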