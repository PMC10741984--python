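"""Dynamic decoupled coordinate system (DDCS) and the decoupled force solve.

In double support the ground reaction is modelled as one pure force at each
foot's center of pressure (COP): M on the left heel-toe segment AB, N on the
right segment CD.  Force-system balance requires the inertial-wrench central
axis to intersect line MN, which couples the two COP parameters: choosing the
left parameter ``a`` (heel-to-COP distance) fixes the right parameter ``b``.

The DDCS is the per-sample frame with origin O at that intersection and X-axis
along the COP-COP line.  There the six force unknowns decouple: the axial sum
FX is directly observable, the four transverse components follow from a full
rank 5x5 linear system, and only the axial split fraction k (and ``a`` itself)
remain free for the energy optimizer.

This module also houses the rank utilities that demonstrate why the balance
system is singular (rank 5 of 6) in *any* ordinary body-fixed frame, which is
the motivation for the DDCS.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .inertial_wrench import Wrench

__all__ = [
    "ContactGeometry",
    "DDCSFrame",
    "DecoupledSystem",
    "ContactSolution",
    "DegenerateGeometryError",
    "coupled_b",
    "contact_geometry",
    "ddcs_frame",
    "solve_decoupled",
    "split_axial",
    "rank_analysis",
    "balance_matrix",
    "rank_invariance",
]


class DegenerateGeometryError(ValueError):
    """Contact geometry does not admit a well-defined DDCS."""


def _unit(v: np.ndarray) -> np.ndarray:
    n = np.linalg.norm(v)
    if n == 0.0:
        raise DegenerateGeometryError("zero-length direction vector")
    return v / n


def _skew(v: np.ndarray) -> np.ndarray:
    x, y, z = v
    return np.array([[0.0, -z, y], [z, 0.0, -x], [-y, x, 0.0]])


# ---------------------------------------------------------------------------
# geometry
# ---------------------------------------------------------------------------

def coupled_b(a: float, *, A, B, C, D, P, f_dir, tol: float = 1e-12) -> float:
    """Right-foot COP parameter ``b`` implied by the left parameter ``a``.

    A pure force at M = A + a*unit(AB) and one at N = C + b*unit(CD) can only
    balance a wrench whose central axis (through P along ``f_dir``) is coplanar
    with M and N; enforcing (PM x PN) . F = 0 yields the closed form

        b = -[(PM x F) . PC] |CD| / [(PM x F) . CD]

    Raises :class:`DegenerateGeometryError` when line CD is (numerically)
    parallel to the plane spanned by PM and F.
    """
    A, B, C, D, P = (np.asarray(x, float) for x in (A, B, C, D, P))
    f = _unit(np.asarray(f_dir, float))
    M = A + a * _unit(B - A)
    n = np.cross(M - P, f)
    CD = D - C
    den = float(n @ CD)
    if abs(den) < tol:
        raise DegenerateGeometryError(
            f"line CD parallel to the plane of PM and F (|denominator| = {abs(den):.3e})")
    return -float(n @ (C - P)) * float(np.linalg.norm(CD)) / den


@dataclass
class ContactGeometry:
    """World-frame double-support contact geometry for one candidate ``a``."""

    A: np.ndarray
    B: np.ndarray
    C: np.ndarray
    D: np.ndarray
    P: np.ndarray  # point on the inertial-wrench central axis
    F_dir: np.ndarray  # unit direction of the central axis
    a: float
    b: float
    M: np.ndarray
    N: np.ndarray

    @property
    def lf_left(self) -> float:
        return float(np.linalg.norm(self.B - self.A))

    @property
    def lf_right(self) -> float:
        return float(np.linalg.norm(self.D - self.C))

    def coplanarity_residual(self) -> float:
        """Normalised |(PM x PN) . F|; ~0 for a consistent (a, b) pair."""
        pm, pn = self.M - self.P, self.N - self.P
        scale = max(np.linalg.norm(pm) * np.linalg.norm(pn), 1e-30)
        return abs(float(np.cross(pm, pn) @ self.F_dir)) / scale


def contact_geometry(a: float, *, A, B, C, D, P, f_dir) -> ContactGeometry:
    """Build the coupled geometry for a candidate left COP parameter ``a``."""
    A, B, C, D, P = (np.asarray(x, float) for x in (A, B, C, D, P))
    f = _unit(np.asarray(f_dir, float))
    b = coupled_b(a, A=A, B=B, C=C, D=D, P=P, f_dir=f)
    M = A + a * _unit(B - A)
    N = C + b * _unit(D - C)
    return ContactGeometry(A=A, B=B, C=C, D=D, P=P, F_dir=f, a=a, b=b, M=M, N=N)


@dataclass
class DDCSFrame:
    """Origin O on the COP-COP line, X along OM, Y normal to plane(P, M, N)."""

    origin: np.ndarray
    axes: np.ndarray  # columns are the world-frame X, Y, Z unit vectors
    l: float  # |OM|
    r: float  # signed: N - O = -r * X (positive when O lies between M and N)

    @property
    def x_axis(self) -> np.ndarray:
        return self.axes[:, 0]

    def wrench_transform(self, ref_point) -> np.ndarray:
        """6x6 map of a world wrench [f; m_ref] to DDCS components about O."""
        Rt = self.axes.T
        ref = np.asarray(ref_point, float)
        T = np.zeros((6, 6))
        T[:3, :3] = Rt
        T[3:, :3] = Rt @ _skew(ref - self.origin)
        T[3:, 3:] = Rt
        return T

    def to_ddcs(self, w: Wrench) -> tuple[np.ndarray, np.ndarray]:
        """(force, moment-about-O) of ``w`` in DDCS axes."""
        m_o = w.moment + np.cross(w.ref_point - self.origin, w.force)
        return self.axes.T @ w.force, self.axes.T @ m_o

    def to_world(self, v_ddcs) -> np.ndarray:
        return self.axes @ np.asarray(v_ddcs, float)


def ddcs_frame(geom: ContactGeometry, gap_tol: float = 1e-8) -> DDCSFrame:
    """Construct the DDCS for a coupled contact geometry.

    O is the closest point on line MN to the central axis; by construction of
    ``b`` the two lines intersect, and the residual gap is checked against
    ``gap_tol`` to catch upstream inconsistencies.
    """
    M, N, P, f = geom.M, geom.N, geom.P, geom.F_dir
    if np.linalg.norm(N - M) < 1e-12:
        raise DegenerateGeometryError("M and N coincide; COP line undefined")
    u = _unit(N - M)
    w0 = M - P
    b1 = float(u @ f)
    denom = 1.0 - b1 * b1
    if denom < 1e-12:
        raise DegenerateGeometryError("central axis parallel to the COP line")
    d1, e1 = float(u @ w0), float(f @ w0)
    t = (b1 * e1 - d1) / denom
    s = (e1 - b1 * d1) / denom
    O = M + t * u
    gap = float(np.linalg.norm(O - (P + s * f)))
    if gap >= gap_tol:
        raise DegenerateGeometryError(
            f"COP line misses the central axis by {gap:.3e} m (inconsistent b upstream)")

    om = M - O
    l = float(np.linalg.norm(om))
    if l < 1e-9:
        raise DegenerateGeometryError("O coincides with M; X-axis undefined")
    X = om / l
    w_axis = P - O
    if np.linalg.norm(w_axis) < 1e-9:
        w_axis = f
    y_raw = np.cross(om, w_axis)
    ny = np.linalg.norm(y_raw)
    if ny < 1e-12:
        raise DegenerateGeometryError("P lies on the X-axis; Y-axis undefined")
    Y = y_raw / ny
    Z = np.cross(X, Y)
    r = -float(X @ (N - O))
    return DDCSFrame(origin=O, axes=np.column_stack([X, Y, Z]), l=l, r=r)


# ---------------------------------------------------------------------------
# decoupled solve
# ---------------------------------------------------------------------------

@dataclass
class DecoupledSystem:
    """The square decoupled balance system A x = FD in DDCS coordinates.

    x  = [FX, FLY, FLZ, FRY, FRZ]     (FX = FLX + FRX, the axial sum)
    FD = [FXD, FYD, FZD, MYD, MZD]    (retained components of the required
                                       total contact wrench about O)
    ``dropped_MXD`` is the X-moment component that pure forces on the X-axis
    cannot produce; it is discarded after the transform and logged as a
    model-error diagnostic.
    """

    A_matrix: np.ndarray
    FD: np.ndarray
    x: np.ndarray
    dropped_MXD: float
    frame: DDCSFrame


def solve_decoupled(frame: DDCSFrame, w: Wrench) -> DecoupledSystem:
    """Solve the five retained balance equations for the contact forces.

        FX            = FXD
        FLY + FRY     = FYD
        FLZ + FRZ     = FZD
        -l FLZ + r FRZ = MYD
         l FLY - r FRY = MZD

    where the right-hand side is the negative inertial wrench expressed in the
    DDCS about O.  Full rank requires l + r > 0 (distinct COPs).
    """
    l, r = frame.l, frame.r
    if abs(l + r) <= 1e-9:  # |MN| = |l + r| with the signed r convention
        raise DegenerateGeometryError(f"coincident COPs (l + r = {l + r:.3e} m): singular system")
    f_d, m_d = frame.to_ddcs(w)
    FD = np.array([-f_d[0], -f_d[1], -f_d[2], -m_d[1], -m_d[2]])
    dropped = -float(m_d[0])
    A = np.array(
        [
            [1.0, 0.0, 0.0, 0.0, 0.0],
            [0.0, 1.0, 0.0, 1.0, 0.0],
            [0.0, 0.0, 1.0, 0.0, 1.0],
            [0.0, 0.0, -l, 0.0, r],
            [0.0, l, 0.0, -r, 0.0],
        ]
    )
    x = np.linalg.solve(A, FD)
    return DecoupledSystem(A_matrix=A, FD=FD, x=x, dropped_MXD=dropped, frame=frame)


def split_axial(sys: DecoupledSystem, k: float):
    """Split the axial force: FLX = k FX, FRX = (1-k) FX.

    Returns ``(f_left_ddcs, f_right_ddcs, f_left_world, f_right_world)``;
    world forces act at M and N respectively.  ``k`` is unconstrained by
    default (the closed-form energy minimizer assumes an unconstrained
    quadratic); clamp externally if friction-plausible output is required.
    """
    FX, FLY, FLZ, FRY, FRZ = sys.x
    fl = np.array([k * FX, FLY, FLZ])
    fr = np.array([(1.0 - k) * FX, FRY, FRZ])
    return fl, fr, sys.frame.to_world(fl), sys.frame.to_world(fr)


# ---------------------------------------------------------------------------
# contact solution container
# ---------------------------------------------------------------------------

@dataclass
class ContactSolution:
    """Per-sample contact force/moment estimate.

    ``f_left``/``f_right`` are world-frame pure forces acting at the COPs
    (the sole-normal free moments are neglected throughout); DDCS components
    are present for double-support samples only.
    """

    phase: str  # "left_single" | "right_single" | "double"
    t: float | None = None
    a: float = np.nan  # left heel-to-COP distance, m
    b: float = np.nan  # right heel-to-COP distance, m
    k: float = np.nan  # axial split fraction
    f_left: np.ndarray = field(default_factory=lambda: np.zeros(3))
    f_right: np.ndarray = field(default_factory=lambda: np.zeros(3))
    f_left_ddcs: np.ndarray | None = None
    f_right_ddcs: np.ndarray | None = None
    cop_left: np.ndarray | None = None
    cop_right: np.ndarray | None = None
    joint_moments: np.ndarray | None = None
    energy: float = np.nan
    dropped_MXD: float = np.nan
    frame: DDCSFrame | None = None
    warnings: tuple[str, ...] = ()


# ---------------------------------------------------------------------------
# rank utilities
# ---------------------------------------------------------------------------

def rank_analysis(a: float, b: float, c: float, d: float) -> int:
    """Numeric rank of the 6x6 double-support force-balance matrix.

    The matrix couples the six unknown foot forces [FLX, FLY, FLZ, FRX, FRY,
    FRZ] to the required resultant [FX, FY, FZ, MX, MY, MZ] for an
    axis-aligned foot placement parameterised by the scalars (a, b, c, d):
    contact points at height -c below the reference, separated by d along the
    travel axis and a/b across it.  For any nonzero scalars the rank is 5 —
    the transverse pair sharing a line of action is unresolvable.
    """
    A = np.array(
        [
            [1, 0, 0, 1, 0, 0],
            [0, 1, 0, 0, 1, 0],
            [0, 0, 1, 0, 0, 1],
            [0, c, b, 0, c, -a],
            [c, 0, -d, c, 0, -d],
            [-b, d, 0, a, d, 0],
        ],
        dtype=float,
    )
    return int(np.linalg.matrix_rank(A))


def balance_matrix(r_left, r_right) -> np.ndarray:
    """6x6 force-only balance matrix for arbitrary 3-D contact points.

    Rows 1-3: force balance [I3 | I3]; rows 4-6: moment balance
    [skew(r_left) | skew(r_right)] about the frame origin.
    """
    r_left, r_right = np.asarray(r_left, float), np.asarray(r_right, float)
    A = np.zeros((6, 6))
    A[:3, :3] = np.eye(3)
    A[:3, 3:] = np.eye(3)
    A[3:, :3] = _skew(r_left)
    A[3:, 3:] = _skew(r_right)
    return A


def rank_invariance(r_left, r_right, rotation) -> tuple[int, int]:
    """Ranks of the balance matrix before and after rotating the frame.

    A homogeneous transformation cannot change the rank, so both values are
    equal (and equal to 5 for distinct contact points): aligning the COP-COP
    line with a coordinate axis does not by itself make the system solvable —
    only merging the collinear components (the DDCS solve) does.
    """
    R = np.asarray(rotation, float)
    A = balance_matrix(r_left, r_right)
    A2 = balance_matrix(R @ np.asarray(r_left, float), R @ np.asarray(r_right, float))
    return int(np.linalg.matrix_rank(A)), int(np.linalg.matrix_rank(A2))
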