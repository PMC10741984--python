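"""Actuated joint moments from kinematics and candidate contact forces.

Implemented as a recursive Newton-Euler style backward pass over the segment
tree: for each actuated DOF the moment is the negative projection, onto the
joint axis, of all D'Alembert (gravity + inertia) wrenches and contact forces
acting on the distal subtree, taken about the joint center.  The classic
``M(q) qdd + C qd + G + F0 = T`` form is realised implicitly by this O(n)
recursion; the matrices are never materialised.

Contact forces are pure forces at the COPs (the sole moments are neglected
throughout the method), so joint moments are an *affine* function of the
contact force vector for fixed kinematics:

    T(f_L, f_R) = T_free + J_L f_L + J_R f_R

The free term and the 3-column Jacobians are exposed separately because the
energy optimizer exploits this affinity; :func:`joint_moments` itself is built
from the same pieces so every caller sees one numeric path.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .body_model import BodyModel, SegmentKinematics

__all__ = ["Contact", "JointMomentResult", "joint_moments",
           "free_joint_moments", "contact_jacobian"]


@dataclass(frozen=True)
class Contact:
    """A world-frame pure force applied at ``point`` on ``segment``."""

    segment: str
    force: np.ndarray
    point: np.ndarray


@dataclass
class JointMomentResult:
    moments: np.ndarray  # (n_dofs,), N*m, model DOF order
    dof_names: list[str]
    joint_classes: list[str]
    contacts: tuple[Contact, ...] = ()


def free_joint_moments(model: BodyModel, kin: SegmentKinematics) -> np.ndarray:
    """Joint moments with no ground contact (D'Alembert loads only).

    Cached on the kinematics object: the free term is reused across the many
    candidate contact placements the optimizer evaluates per sample.
    """
    cached = getattr(kin, "_free_moments_cache", None)
    if cached is not None:
        return cached

    g = model.gravity
    # per-segment load resultants: S_F = sum F_i, S_M = sum (c_i x F_i + tau_i)
    seg_F: dict[str, np.ndarray] = {}
    seg_M: dict[str, np.ndarray] = {}
    for name, seg in model.segments.items():
        st = kin.segments[name]
        f_i = seg.mass * (g - st.com_acc)
        Iw = st.R @ seg.inertia @ st.R.T
        tau_i = -(Iw @ st.alpha + np.cross(st.omega, Iw @ st.omega))
        seg_F[name] = f_i
        seg_M[name] = np.cross(st.com, f_i) + tau_i

    # subtree aggregates by leaf-to-root accumulation
    agg_F = {n: seg_F[n].copy() for n in model.order}
    agg_M = {n: seg_M[n].copy() for n in model.order}
    for name in reversed(model.order):
        p = model.segments[name].parent
        if p is not None:
            agg_F[p] += agg_F[name]
            agg_M[p] += agg_M[name]

    T = np.empty(model.n_dofs)
    for j, ds in enumerate(kin.dofs):
        m = agg_M[ds.segment] - np.cross(ds.anchor_world, agg_F[ds.segment])
        T[j] = -float(ds.axis_world @ m)
    kin._free_moments_cache = T
    return T


def contact_jacobian(model: BodyModel, kin: SegmentKinematics, segment: str, point) -> np.ndarray:
    """(n_dofs, 3) map from a world force at ``point`` on ``segment`` to joint moments.

    Row j is ``-axis_j x (point - anchor_j)`` when ``segment`` lies in DOF j's
    distal subtree, else zero.
    """
    point = np.asarray(point, float)
    if not np.all(np.isfinite(point)):
        raise ValueError("contact application point must be finite")
    J = np.zeros((model.n_dofs, 3))
    for j, ds in enumerate(kin.dofs):
        if segment in model.subtree(ds.segment):
            J[j] = -np.cross(ds.axis_world, point - ds.anchor_world)
    return J


def joint_moments(model: BodyModel, kin: SegmentKinematics,
                  contacts: tuple[Contact, ...] | list[Contact] = ()) -> JointMomentResult:
    """Actuated joint moments for the sample's kinematics and given contacts."""
    T = free_joint_moments(model, kin).copy()
    for c in contacts:
        f = np.asarray(c.force, float)
        T += contact_jacobian(model, kin, c.segment, c.point) @ f
    return JointMomentResult(
        moments=T,
        dof_names=list(model.dof_names),
        joint_classes=list(model.dof_classes),
        contacts=tuple(contacts),
    )
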