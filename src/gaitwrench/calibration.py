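"""Grid-traversal calibration of the joint weight factors [q0, q1, q2].

The weights enter the estimator only through the energy objective, so they
can only be identified from samples where the objective actually selects the
solution — double support.  Calibration therefore traverses a (q1, q2) grid
(hip flexion/extension fixed at 1 as the scale reference, hip ab/adduction
q0 fixed by default as well), re-estimates every double-support sample, and
scores the mean squared error between estimated and reference contact forces
over the six world-frame components.

Because the energy argmin is invariant to scaling all weights by c > 0, only
weight *ratios* are identifiable; fixing the hip flexion weight removes the
degeneracy.  The default grid is the flat (0, 5] x (0, 5] traversal at
interval 0.1 (50 x 50 = 2500 combinations).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .body_model import BodyModel, forward_kinematics
from .ddcs_solver import DegenerateGeometryError
from .energy_optimizer import (DoubleSupportProblem, EnergyModel, EstimationError,
                               NoFeasibleCopError, build_problem, solve_with_factors)
from .inertial_wrench import PureCoupleError, aggregate_inertial_wrench, central_axis_reduction
from .support_detector import DOUBLE, NoPiercePointError, classify_support

__all__ = ["CalibrationResult", "calibrate_factors", "default_q_grid"]


def default_q_grid(q_max: float = 5.0, q_step: float = 0.1) -> np.ndarray:
    """The traversal grid over (0, q_max]: {q_step, 2 q_step, ..., q_max}."""
    n = int(round(q_max / q_step))
    return np.round(np.arange(1, n + 1) * q_step, 10)


@dataclass
class CalibrationResult:
    factors: tuple[float, float, float]  # (q0, q1, q2)
    objective: float  # mean squared force error, N^2
    q1_values: np.ndarray
    q2_values: np.ndarray
    objective_grid: np.ndarray  # (len(q1_values), len(q2_values))
    n_samples: int  # double-support samples actually scored


def _reference_forces(reference) -> tuple[np.ndarray, np.ndarray]:
    if isinstance(reference, pd.DataFrame):
        fl = reference[["flx", "fly", "flz"]].to_numpy(float)
        fr = reference[["frx", "fry", "frz"]].to_numpy(float)
        return fl, fr
    fl = np.array([np.asarray(r.f_left, float) for r in reference])
    fr = np.array([np.asarray(r.f_right, float) for r in reference])
    return fl, fr


def calibrate_factors(model: BodyModel, samples, reference,
                      q1_values: np.ndarray | None = None,
                      q2_values: np.ndarray | None = None,
                      q0: float = 1.0,
                      grid_step: float | None = None) -> CalibrationResult:
    """Fit (q1, q2) by exhaustive traversal against reference contact forces.

    ``reference`` is aligned sample-by-sample with ``samples`` (estimator
    output CSV layout or any sequence with ``f_left``/``f_right``).  Ties in
    the objective break toward smaller q1, then smaller q2.
    """
    q1_values = default_q_grid() if q1_values is None else np.asarray(q1_values, float)
    q2_values = default_q_grid() if q2_values is None else np.asarray(q2_values, float)
    if q1_values.size == 0 or q2_values.size == 0:
        raise ValueError("empty calibration grid")
    ref_l, ref_r = _reference_forces(reference)
    if len(ref_l) != len(samples):
        raise ValueError(f"reference table has {len(ref_l)} rows but motion has {len(samples)} samples")

    # precompute the factor-independent part of every double-support sample
    problems: list[tuple[DoubleSupportProblem, np.ndarray, np.ndarray]] = []
    for i, s in enumerate(samples):
        try:
            kin = forward_kinematics(model, s)
            w = aggregate_inertial_wrench(model, kin)
            caw = central_axis_reduction(w)
            state = classify_support(caw, kin)
            if state.phase != DOUBLE:
                continue
            if not (np.all(np.isfinite(ref_l[i])) and np.all(np.isfinite(ref_r[i]))):
                continue
            problems.append((build_problem(model, kin, w, caw, grid_step=grid_step, t=s.t,
                                           state=state), ref_l[i], ref_r[i]))
        except (NoFeasibleCopError, EstimationError, DegenerateGeometryError,
                PureCoupleError, NoPiercePointError):
            continue
    if not problems:
        raise ValueError("no usable double-support samples for calibration")

    grid = np.empty((q1_values.size, q2_values.size))
    for i1, q1 in enumerate(q1_values):
        for i2, q2 in enumerate(q2_values):
            em = EnergyModel.from_q(q0=q0, q1=float(q1), q2=float(q2))
            se = 0.0
            for problem, rl, rr in problems:
                try:
                    sol = solve_with_factors(problem, em)
                except EstimationError:
                    se = np.inf
                    break
                dl = sol.f_left - rl
                dr = sol.f_right - rr
                se += float(dl @ dl + dr @ dr)
            grid[i1, i2] = se / (6.0 * len(problems))

    best = np.unravel_index(int(np.argmin(grid)), grid.shape)  # row-major: smallest q1 then q2
    return CalibrationResult(
        factors=(q0, float(q1_values[best[0]]), float(q2_values[best[1]])),
        objective=float(grid[best]),
        q1_values=q1_values,
        q2_values=q2_values,
        objective_grid=grid,
        n_samples=len(problems),
    )
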