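"""Resultant D'Alembert wrench of the whole body and its central-axis reduction.

The per-segment "inertia force" includes gravity, F_i = m_i (g - a_i), so the
ground contact wrench of a balanced pose is exactly the negative of the
aggregate.  The aggregate wrench about the reference point O0 is then reduced
to its central (screw) axis: a force F, a couple T collinear with F, and the
perpendicular offset p of the axis from O0 (Poinsot reduction).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .body_model import BodyModel, SegmentKinematics

__all__ = ["Wrench", "CentralAxisWrench", "PureCoupleError",
           "aggregate_inertial_wrench", "central_axis_reduction"]


class PureCoupleError(ValueError):
    """The wrench has (numerically) no force; the central axis is undefined."""


@dataclass
class Wrench:
    """A force and a moment expressed about ``ref_point`` (world frame)."""

    force: np.ndarray
    moment: np.ndarray
    ref_point: np.ndarray

    def about(self, point) -> "Wrench":
        """Re-express the same wrench about another reference point."""
        point = np.asarray(point, dtype=float)
        moment = self.moment + np.cross(self.ref_point - point, self.force)
        return Wrench(force=self.force.copy(), moment=moment, ref_point=point)

    def __add__(self, other: "Wrench") -> "Wrench":
        o = other.about(self.ref_point)
        return Wrench(self.force + o.force, self.moment + o.moment, self.ref_point)


@dataclass
class CentralAxisWrench:
    """Reduced wrench: force ``force`` along the central axis through
    ``ref_point + axis_point``, plus the collinear couple ``couple``.

    Invariants: couple x force = 0 and axis_point . force = 0.
    """

    force: np.ndarray
    couple: np.ndarray
    axis_point: np.ndarray  # perpendicular offset p of the axis from ref_point
    ref_point: np.ndarray

    @property
    def point(self) -> np.ndarray:
        """A world point on the central axis (P = O0 + p)."""
        return self.ref_point + self.axis_point

    @property
    def direction(self) -> np.ndarray:
        return self.force / np.linalg.norm(self.force)


def aggregate_inertial_wrench(model: BodyModel, kin: SegmentKinematics) -> Wrench:
    """Sum all segment D'Alembert wrenches into one wrench about O0.

    force  = sum_i m_i (g - a_i)
    moment = sum_i d_i x F_i + sum_i tau_i,   tau_i = -(I_i alpha_i + w_i x I_i w_i)

    with d_i the vector from O0 to segment i's com and I_i the world-frame
    inertia tensor about the com.
    """
    g = model.gravity
    o0 = kin.o0
    F = np.zeros(3)
    M = np.zeros(3)
    for name, seg in model.segments.items():
        st = kin.segments[name]
        f_i = seg.mass * (g - st.com_acc)
        Iw = st.R @ seg.inertia @ st.R.T
        tau_i = -(Iw @ st.alpha + np.cross(st.omega, Iw @ st.omega))
        F += f_i
        M += np.cross(st.com - o0, f_i) + tau_i
    return Wrench(force=F, moment=M, ref_point=o0.copy())


def central_axis_reduction(w: Wrench, force_tol: float = 1e-9) -> CentralAxisWrench:
    """Poinsot reduction of ``w`` to its central axis.

    couple = ((F . M)/|F|^2) F        (component of the moment along the force)
    p      = (F x M)/|F|^2            (perpendicular offset of the axis)

    The pair (F acting through ref_point + p, plus the couple) is equipollent
    to ``w``.  Raises :class:`PureCoupleError` when |F| < ``force_tol`` (the
    axis is undefined, e.g. free-fall-like states).
    """
    F, M = w.force, w.moment
    f2 = float(F @ F)
    if f2 < force_tol**2:
        raise PureCoupleError(f"|force| = {np.sqrt(f2):.3e} N below tolerance; pure couple has no central axis")
    couple = (float(F @ M) / f2) * F
    p = np.cross(F, M) / f2
    return CentralAxisWrench(force=F.copy(), couple=couple, axis_point=p, ref_point=w.ref_point.copy())
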