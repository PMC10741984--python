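"""Support-phase classification from the inertial-wrench central axis.

The central axis of the whole-body D'Alembert wrench pierces the ground plane
at the "subpoint".  When that point falls inside one foot's sole contour it is
that foot's center of pressure and the sample is single support with a
closed-form, exact contact solution; otherwise the sample is treated as double
support and handed to the optimizer.

Classification is per-sample and stateless (no temporal hysteresis), and
depends only on the direction of the force, not its magnitude.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from shapely.geometry import Point, Polygon

from .body_model import SegmentKinematics
from .ddcs_solver import ContactSolution
from .inertial_wrench import CentralAxisWrench, Wrench

__all__ = ["SupportState", "NoPiercePointError", "classify_support", "single_support_solution",
           "LEFT_SINGLE", "RIGHT_SINGLE", "DOUBLE"]

LEFT_SINGLE = "left_single"
RIGHT_SINGLE = "right_single"
DOUBLE = "double"

#: boundary band (m): pierce points within this distance of a contour edge
#: count as inside, since misclassification at phase transitions is the
#: method's known failure mode.
EDGE_TOLERANCE = 1e-3


class NoPiercePointError(ValueError):
    """The central axis is parallel to the ground plane."""


@dataclass
class SupportState:
    phase: str
    pierce_point: np.ndarray  # on the ground plane z = 0
    inside_flags: dict[str, bool]
    warning: str | None = None


def classify_support(caw: CentralAxisWrench, kin: SegmentKinematics,
                     edge_tol: float = EDGE_TOLERANCE) -> SupportState:
    """Classify a sample as left/right single support or double support.

    The pierce point is the intersection of the central axis with z = 0;
    point-in-polygon is boundary-inclusive with an ``edge_tol`` band.  A
    pierce point inside neither contour yields double support; if it is also
    not between the feet along the inter-foot direction the state carries a
    diagnostic warning (the estimate remains usable but the geometry is
    suspect).
    """
    F = caw.force
    if abs(F[2]) < 1e-9:
        raise NoPiercePointError("central axis parallel to the ground plane (|F_z| < 1e-9 N)")
    P0 = caw.point
    s = -P0[2] / F[2]
    pierce = P0 + s * F
    pt = Point(pierce[0], pierce[1])

    inside = {}
    for side, foot in kin.feet.items():
        poly = Polygon(foot.contour[:, :2])
        inside[side] = bool(poly.buffer(edge_tol).covers(pt))

    warning = None
    if inside["left"] and not inside["right"]:
        phase = LEFT_SINGLE
    elif inside["right"] and not inside["left"]:
        phase = RIGHT_SINGLE
    else:
        phase = DOUBLE
        if inside["left"] and inside["right"]:
            warning = "pierce point inside both foot contours"
        else:
            c_l = kin.feet["left"].contour[:, :2].mean(axis=0)
            c_r = kin.feet["right"].contour[:, :2].mean(axis=0)
            d = c_r - c_l
            u = float((pierce[:2] - c_l) @ d) / max(float(d @ d), 1e-30)
            if not (0.0 <= u <= 1.0):
                warning = "pierce point outside both feet and not between them"
    return SupportState(phase=phase, pierce_point=pierce, inside_flags=inside, warning=warning)


def single_support_solution(w: Wrench, caw: CentralAxisWrench, state: SupportState,
                            kin: SegmentKinematics) -> ContactSolution:
    """Closed-form, exact contact solution for a single-support sample.

    The stance-foot force is -F applied at the pierce point (which is the
    COP); the swing foot carries nothing; the two sole-plane moment
    components are zero by construction and the along-axis couple is the
    (neglected) residual.  No optimization is involved.
    """
    if state.phase not in (LEFT_SINGLE, RIGHT_SINGLE):
        raise ValueError(f"single_support_solution called in phase {state.phase!r}")
    side = "left" if state.phase == LEFT_SINGLE else "right"
    foot = kin.feet[side]
    axis = foot.toe - foot.heel
    cop_param = float((state.pierce_point - foot.heel) @ axis) / float(np.linalg.norm(axis))

    force = -w.force
    sol = ContactSolution(phase=state.phase)
    sol.dropped_MXD = float(np.linalg.norm(caw.couple))
    if side == "left":
        sol.f_left = force
        sol.cop_left = state.pierce_point.copy()
        sol.a = cop_param
        sol.k = 1.0
    else:
        sol.f_right = force
        sol.cop_right = state.pierce_point.copy()
        sol.b = cop_param
        sol.k = 0.0
    if state.warning:
        sol.warnings = (state.warning,)
    return sol
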