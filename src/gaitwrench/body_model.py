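"""Articulated rigid-body model of a human(-exoskeleton) system and its kinematics.

The body is a tree of rigid segments rooted at a floating base (typically the
pelvis).  Each segment attaches to its parent through an ordered sequence of
revolute degrees of freedom; successive axes compose intrinsically (each axis
rotates with the preceding rotations of the same joint), so a 2-DOF hip listed
as flexion-then-adduction behaves like a gimbal chain.

World frame convention: right-handed, Z up, ground plane z = 0, gravity
(0, 0, -9.81) m/s^2 by default.  All quantities are SI (m, kg, s, rad).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import yaml
from shapely.geometry import LineString, Polygon

__all__ = [
    "Dof",
    "Segment",
    "FootDefinition",
    "BodyModel",
    "MotionSample",
    "SegmentState",
    "DofState",
    "FootPoints",
    "SegmentKinematics",
    "ModelValidationError",
    "load_model",
    "forward_kinematics",
    "rotation_about_axis",
    "as_rotation_matrix",
]

#: joint classes recognised by the energy model
JOINT_CLASSES = ("hip_fe", "hip_aa", "knee", "ankle", "other")


class ModelValidationError(ValueError):
    """A body-model configuration violates a structural invariant."""


def _vec3(x, name: str) -> np.ndarray:
    v = np.asarray(x, dtype=float)
    if v.shape != (3,):
        raise ModelValidationError(f"{name}: expected a 3-vector, got shape {v.shape}")
    return v


def rotation_about_axis(axis: np.ndarray, angle: float) -> np.ndarray:
    """Rodrigues rotation matrix about a unit axis."""
    x, y, z = axis
    c, s = math.cos(angle), math.sin(angle)
    C = 1.0 - c
    return np.array(
        [
            [c + x * x * C, x * y * C - z * s, x * z * C + y * s],
            [y * x * C + z * s, c + y * y * C, y * z * C - x * s],
            [z * x * C - y * s, z * y * C + x * s, c + z * z * C],
        ]
    )


def as_rotation_matrix(orientation) -> np.ndarray:
    """Accept a 3x3 matrix or a unit quaternion (w, x, y, z) and return a matrix."""
    q = np.asarray(orientation, dtype=float)
    if q.shape == (3, 3):
        return q
    if q.shape == (4,):
        w, x, y, z = q / np.linalg.norm(q)
        return np.array(
            [
                [1 - 2 * (y * y + z * z), 2 * (x * y - w * z), 2 * (x * z + w * y)],
                [2 * (x * y + w * z), 1 - 2 * (x * x + z * z), 2 * (y * z - w * x)],
                [2 * (x * z - w * y), 2 * (y * z + w * x), 1 - 2 * (x * x + y * y)],
            ]
        )
    raise ModelValidationError(f"orientation: expected 3x3 matrix or quaternion, got shape {q.shape}")


@dataclass(frozen=True)
class Dof:
    """One actuated revolute degree of freedom."""

    name: str
    axis: np.ndarray  # unit 3-vector in the frame preceding this rotation
    joint_class: str = "other"


@dataclass
class Segment:
    """A rigid segment attached to its parent by zero or more revolute DOFs."""

    name: str
    parent: str | None
    joint_origin: np.ndarray  # in parent frame
    dofs: tuple[Dof, ...]
    mass: float
    com: np.ndarray  # in segment frame
    inertia: np.ndarray  # 3x3 about the com, segment frame
    length: float = 0.0

    @property
    def joint_axes(self) -> list[np.ndarray]:
        return [d.axis for d in self.dofs]


@dataclass
class FootDefinition:
    """Heel-toe segment plus a 6-point sole contour, all in the foot frame."""

    side: str  # "left" | "right"
    segment: str  # name of the carrying segment
    heel: np.ndarray
    toe: np.ndarray
    contour: np.ndarray  # (6, 3), ordered simple polygon in the sole plane

    @property
    def lf(self) -> float:
        """Foot length |toe - heel| (the heel-toe contact segment length)."""
        return float(np.linalg.norm(self.toe - self.heel))


@dataclass
class BodyModel:
    """Validated segment tree with two feet.

    ``dofs`` enumerates the actuated DOFs in depth-first segment order; motion
    tables and joint-moment vectors follow this ordering.
    """

    segments: dict[str, Segment]
    order: list[str]  # topological order, root first
    feet: dict[str, FootDefinition]  # keys "left", "right"
    gravity: np.ndarray
    origin_segment: str

    def __post_init__(self):
        self.dofs: list[tuple[str, Dof]] = []  # (segment name, dof)
        for name in self.order:
            for d in self.segments[name].dofs:
                self.dofs.append((name, d))
        self.dof_names = [d.name for _, d in self.dofs]
        self.dof_classes = [d.joint_class for _, d in self.dofs]
        self._children: dict[str, list[str]] = {n: [] for n in self.order}
        for name in self.order:
            p = self.segments[name].parent
            if p is not None:
                self._children[p].append(name)
        self._subtrees: dict[str, frozenset[str]] = {}
        for name in reversed(self.order):
            members = {name}
            for c in self._children[name]:
                members |= self._subtrees[c]
            self._subtrees[name] = frozenset(members)

    @property
    def root(self) -> str:
        return self.order[0]

    @property
    def n_dofs(self) -> int:
        return len(self.dofs)

    @property
    def total_mass(self) -> float:
        return float(sum(s.mass for s in self.segments.values()))

    def children(self, name: str) -> list[str]:
        return self._children[name]

    def subtree(self, name: str) -> frozenset[str]:
        """Names of ``name`` and every segment distal to it."""
        return self._subtrees[name]

    def foot(self, side: str) -> FootDefinition:
        return self.feet[side]


@dataclass
class MotionSample:
    """One time-stamped whole-body state.

    Base (floating-base) velocity/acceleration terms default to zero; the
    motion reader fills them by smoothing differentiation when the table
    carries base pose columns.
    """

    t: float
    base_position: np.ndarray
    base_orientation: np.ndarray  # 3x3 or quaternion (w,x,y,z)
    theta: np.ndarray
    theta_dot: np.ndarray
    theta_ddot: np.ndarray
    base_lin_vel: np.ndarray = field(default_factory=lambda: np.zeros(3))
    base_lin_acc: np.ndarray = field(default_factory=lambda: np.zeros(3))
    base_ang_vel: np.ndarray = field(default_factory=lambda: np.zeros(3))
    base_ang_acc: np.ndarray = field(default_factory=lambda: np.zeros(3))


@dataclass
class SegmentState:
    """World-frame state of one segment (frame origin = its joint origin)."""

    R: np.ndarray
    origin: np.ndarray
    com: np.ndarray
    com_vel: np.ndarray
    com_acc: np.ndarray
    omega: np.ndarray
    alpha: np.ndarray
    origin_vel: np.ndarray
    origin_acc: np.ndarray


@dataclass
class DofState:
    """World-frame axis and anchor of one actuated DOF."""

    name: str
    segment: str
    joint_class: str
    axis_world: np.ndarray
    anchor_world: np.ndarray  # joint-center position


@dataclass
class FootPoints:
    heel: np.ndarray
    toe: np.ndarray
    contour: np.ndarray  # (6, 3) world


@dataclass
class SegmentKinematics:
    """Output of :func:`forward_kinematics` for one motion sample."""

    segments: dict[str, SegmentState]
    dofs: list[DofState]
    feet: dict[str, FootPoints]
    o0: np.ndarray  # world position of the wrench reference point O0


# ---------------------------------------------------------------------------
# model loading / validation
# ---------------------------------------------------------------------------

def _parse_inertia(raw, name: str) -> np.ndarray:
    arr = np.asarray(raw, dtype=float)
    if arr.shape == (6,):  # [ixx, iyy, izz, ixy, ixz, iyz]
        ixx, iyy, izz, ixy, ixz, iyz = arr
        arr = np.array([[ixx, ixy, ixz], [ixy, iyy, iyz], [ixz, iyz, izz]])
    if arr.shape != (3, 3):
        raise ModelValidationError(f"{name}.inertia: expected 3x3 or 6-vector")
    if not np.allclose(arr, arr.T, atol=1e-12):
        raise ModelValidationError(f"{name}.inertia: tensor must be symmetric")
    if np.min(np.linalg.eigvalsh(arr)) < -1e-12:
        raise ModelValidationError(f"{name}.inertia: tensor must be positive semidefinite")
    return arr


def _parse_segment(raw: Mapping) -> Segment:
    name = raw["name"]
    dofs = []
    for d in raw.get("dofs", []):
        axis = _vec3(d["axis"], f"{name}.dofs.axis")
        n = np.linalg.norm(axis)
        if abs(n - 1.0) > 1e-8:
            raise ModelValidationError(f"{name}.dofs[{d.get('name')}]: non-unit joint axis (|axis|={n:.6g})")
        dofs.append(Dof(name=d["name"], axis=axis, joint_class=d.get("joint_class", "other")))
    mass = float(raw.get("mass", 0.0))
    if mass < 0:
        raise ModelValidationError(f"{name}.mass: must be >= 0")
    return Segment(
        name=name,
        parent=raw.get("parent"),
        joint_origin=_vec3(raw.get("joint_origin", (0, 0, 0)), f"{name}.joint_origin"),
        dofs=tuple(dofs),
        mass=mass,
        com=_vec3(raw.get("com", (0, 0, 0)), f"{name}.com"),
        inertia=_parse_inertia(raw.get("inertia", np.zeros((3, 3))), name),
        length=float(raw.get("length", 0.0)),
    )


def _parse_foot(raw: Mapping) -> FootDefinition:
    side = raw["side"]
    if side not in ("left", "right"):
        raise ModelValidationError(f"feet.side: must be 'left' or 'right', got {side!r}")
    heel = _vec3(raw["heel"], f"feet[{side}].heel")
    toe = _vec3(raw["toe"], f"feet[{side}].toe")
    contour = np.asarray(raw["contour"], dtype=float)
    if contour.shape != (6, 3):
        raise ModelValidationError(f"feet[{side}].contour: expected 6 points, got shape {contour.shape}")
    foot = FootDefinition(side=side, segment=raw["segment"], heel=heel, toe=toe, contour=contour)
    if foot.lf <= 0:
        raise ModelValidationError(f"feet[{side}]: lf = |toe - heel| must be > 0")
    poly = Polygon(contour[:, :2])
    if not poly.is_valid:
        raise ModelValidationError(f"feet[{side}].contour: polygon is self-intersecting")
    if not poly.buffer(1e-9).covers(LineString([heel[:2], toe[:2]])):
        raise ModelValidationError(f"feet[{side}].contour: must contain the heel-toe segment")
    return foot


def load_model(config_source) -> BodyModel:
    """Load and validate a body model from a dict, YAML/JSON text, or a file path.

    Raises :class:`ModelValidationError` naming the offending field on any
    structural violation (cycle in the segment graph, missing foot, non-unit
    joint axis, ...).
    """
    if isinstance(config_source, Mapping):
        cfg = config_source
    else:
        p = Path(str(config_source))
        text = p.read_text() if p.exists() else str(config_source)
        cfg = yaml.safe_load(text)
    if not isinstance(cfg, Mapping) or "segments" not in cfg:
        raise ModelValidationError("config: missing 'segments'")

    segments = {}
    for raw in cfg["segments"]:
        seg = _parse_segment(raw)
        if seg.name in segments:
            raise ModelValidationError(f"segments: duplicate name {seg.name!r}")
        if seg.parent == seg.name:
            raise ModelValidationError(f"segments: cycle in segment graph at {seg.name!r} (self-parent)")
        segments[seg.name] = seg

    roots = [s.name for s in segments.values() if s.parent is None]
    if len(roots) != 1:
        raise ModelValidationError(f"segments: expected exactly one floating base, found {roots}")
    for seg in segments.values():
        if seg.parent is not None and seg.parent not in segments:
            raise ModelValidationError(f"{seg.name}.parent: unknown segment {seg.parent!r}")

    # topological order with cycle detection
    order: list[str] = []
    state: dict[str, int] = {}

    def visit(name: str, trail: tuple[str, ...]):
        if name in trail:
            raise ModelValidationError(f"segments: cycle in segment graph at {name!r}")
        if state.get(name):
            return
        seg = segments[name]
        if seg.parent is not None:
            visit(seg.parent, trail + (name,))
        state[name] = 1
        order.append(name)

    for name in segments:
        visit(name, ())
    if segments[order[0]].dofs:
        raise ModelValidationError("base segment must not carry actuated DOFs (it is the floating base)")

    feet = {}
    for raw in cfg.get("feet", []):
        foot = _parse_foot(raw)
        if foot.segment not in segments:
            raise ModelValidationError(f"feet[{foot.side}].segment: unknown segment {foot.segment!r}")
        feet[foot.side] = foot
    for side in ("left", "right"):
        if side not in feet:
            raise ModelValidationError(f"feet: missing {side} foot")

    gravity = _vec3(cfg.get("gravity", (0.0, 0.0, -9.81)), "gravity")
    origin_segment = cfg.get("origin_segment", order[0])
    if origin_segment not in segments:
        raise ModelValidationError(f"origin_segment: unknown segment {origin_segment!r}")

    return BodyModel(segments=segments, order=order, feet=feet, gravity=gravity, origin_segment=origin_segment)


# ---------------------------------------------------------------------------
# forward kinematics
# ---------------------------------------------------------------------------

def forward_kinematics(model: BodyModel, sample: MotionSample) -> SegmentKinematics:
    """Propagate world poses, velocities and accelerations through the tree.

    Angular velocity/acceleration and com acceleration are propagated
    analytically (revolute-chain recursion), so they are exactly consistent
    with the pose chain; a finite-difference check on any smooth trajectory
    agrees to O(dt^2).
    """
    nq = model.n_dofs
    for arr, nm in ((sample.theta, "theta"), (sample.theta_dot, "theta_dot"), (sample.theta_ddot, "theta_ddot")):
        if np.shape(arr) != (nq,):
            raise ValueError(f"sample.{nm}: expected {nq} DOFs, got shape {np.shape(arr)}")

    states: dict[str, SegmentState] = {}
    dof_states: list[DofState] = []

    R0 = as_rotation_matrix(sample.base_orientation)
    p0 = np.asarray(sample.base_position, dtype=float)
    root = model.segments[model.root]
    states[model.root] = _segment_state(
        root, R0, p0,
        np.asarray(sample.base_ang_vel, float), np.asarray(sample.base_ang_acc, float),
        np.asarray(sample.base_lin_vel, float), np.asarray(sample.base_lin_acc, float),
    )

    idx = 0
    for name in model.order[1:]:
        seg = model.segments[name]
        par = states[seg.parent]
        d = par.R @ seg.joint_origin
        o = par.origin + d
        v_o = par.origin_vel + np.cross(par.omega, d)
        a_o = par.origin_acc + np.cross(par.alpha, d) + np.cross(par.omega, np.cross(par.omega, d))

        R, w, al = par.R, par.omega, par.alpha
        for dof in seg.dofs:
            axis_w = R @ dof.axis
            th, thd, thdd = sample.theta[idx], sample.theta_dot[idx], sample.theta_ddot[idx]
            al = al + thdd * axis_w + np.cross(w, thd * axis_w)
            w = w + thd * axis_w
            R = R @ rotation_about_axis(dof.axis, th)
            dof_states.append(DofState(dof.name, name, dof.joint_class, axis_w, o))
            idx += 1
        states[name] = _segment_state(seg, R, o, w, al, v_o, a_o)

    feet = {}
    for side, foot in model.feet.items():
        st = states[foot.segment]
        feet[side] = FootPoints(
            heel=st.origin + st.R @ foot.heel,
            toe=st.origin + st.R @ foot.toe,
            contour=st.origin + foot.contour @ st.R.T,
        )
    o0 = states[model.origin_segment].origin
    return SegmentKinematics(segments=states, dofs=dof_states, feet=feet, o0=o0)


def _segment_state(seg: Segment, R, o, w, al, v_o, a_o) -> SegmentState:
    r = R @ seg.com
    return SegmentState(
        R=R, origin=o,
        com=o + r,
        com_vel=v_o + np.cross(w, r),
        com_acc=a_o + np.cross(al, r) + np.cross(w, np.cross(w, r)),
        omega=w, alpha=al, origin_vel=v_o, origin_acc=a_o,
    )
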