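"""Synthetic walking data: body models, motion, and ground-truth contact forces.

Everything downstream of the estimator is testable without any external
dataset: this module generates (1) an anthropometric 12-segment body model
from height and mass, (2) kinematically consistent walking trajectories, and
(3) ground-truth contact wrenches that satisfy the same balance equations the
estimator enforces.

Gait synthesis is task-space: pelvis and ankle trajectories are designed
(constant forward speed, lateral sway toward the stance foot, vertical bob,
C2-smooth swing profiles), joint angles follow by inverse kinematics of each
3-DOF leg chain, and every joint/base channel is then refit as a truncated
Fourier series over the gait cycle.  The published trajectories are therefore
exactly periodic sums of low-order harmonics with analytic velocities and
accelerations, while the feet stay on the ground during their stance windows
to within the (small) harmonic-truncation residual.

The kinematics are exercise-grade, not biofidelic: no claim of matching human
gait datasets is made or tested.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .body_model import BodyModel, MotionSample, forward_kinematics, load_model
from .ddcs_solver import DegenerateGeometryError, contact_geometry, ddcs_frame, solve_decoupled, split_axial
from .energy_optimizer import (EnergyModel, NoFeasibleCopError, build_problem,
                               feasible_a_range, EstimationError)
from .inertial_wrench import PureCoupleError, aggregate_inertial_wrench, central_axis_reduction
from .support_detector import DOUBLE, LEFT_SINGLE, NoPiercePointError, classify_support, single_support_solution

__all__ = ["GaitParams", "TruthRecord", "generate_model", "generate_gait", "generate_truth"]


# ---------------------------------------------------------------------------
# anthropometric model
# ---------------------------------------------------------------------------

# Segment mass fractions (Winter-style anthropometric tables, hand/forearm and
# head/trunk merged); they sum to exactly 1.
MASS_FRACTIONS = {
    "pelvis": 0.142,
    "torso": 0.436,  # trunk + head + neck
    "upper_arm": 0.028,  # each
    "forearm": 0.022,  # each, incl. hand
    "thigh": 0.100,  # each
    "shank": 0.0465,  # each
    "foot": 0.0145,  # each
}

# Segment length fractions of standing height.
LENGTH_FRACTIONS = {
    "thigh": 0.245,
    "shank": 0.246,
    "foot": 0.152,
    "ankle_height": 0.039,
    "hip_halfwidth": 0.045,
    "upper_arm": 0.186,
    "forearm": 0.216,
}


def _rod_inertia(mass: float, length: float, axial_frac: float = 0.1) -> list:
    """Slender-rod tensor about the com, long axis = local Z."""
    it = mass * length**2 / 12.0
    return [[it, 0, 0], [0, it, 0], [0, 0, axial_frac * it]]


def _box_inertia(mass: float, lx: float, ly: float, lz: float) -> list:
    return [
        [mass * (ly**2 + lz**2) / 12.0, 0, 0],
        [0, mass * (lx**2 + lz**2) / 12.0, 0],
        [0, 0, mass * (lx**2 + ly**2) / 12.0],
    ]


def generate_model(height: float, mass: float) -> dict:
    """Anthropometric 12-segment body-model config (dict; feed to load_model).

    Segments: pelvis (floating base), torso (incl. head), welded arms, and
    per leg a thigh (2-DOF hip: flexion/extension then ab/adduction), shank
    (1-DOF knee) and foot (1-DOF ankle) — 8 actuated DOFs.  Total mass equals
    ``mass`` exactly; foot contours have six vertices.
    """
    if not (0.5 <= height <= 2.5):
        raise ValueError(f"height {height} m outside plausible range [0.5, 2.5]")
    if not (10.0 <= mass <= 200.0):
        raise ValueError(f"mass {mass} kg outside plausible range [10, 200]")

    H = height
    lt = LENGTH_FRACTIONS["thigh"] * H
    ls = LENGTH_FRACTIONS["shank"] * H
    lf = LENGTH_FRACTIONS["foot"] * H
    ha = LENGTH_FRACTIONS["ankle_height"] * H
    hw = LENGTH_FRACTIONS["hip_halfwidth"] * H
    lua = LENGTH_FRACTIONS["upper_arm"] * H
    lfa = LENGTH_FRACTIONS["forearm"] * H

    segments = [
        dict(name="pelvis", parent=None, joint_origin=[0, 0, 0], dofs=[],
             mass=MASS_FRACTIONS["pelvis"] * mass, com=[0, 0, 0],
             inertia=_box_inertia(MASS_FRACTIONS["pelvis"] * mass, 0.15 * H, 0.19 * H, 0.1 * H),
             length=0.1 * H),
        dict(name="torso", parent="pelvis", joint_origin=[0, 0, 0.03 * H], dofs=[],
             mass=MASS_FRACTIONS["torso"] * mass, com=[0, 0, 0.22 * H],
             inertia=_box_inertia(MASS_FRACTIONS["torso"] * mass, 0.15 * H, 0.2 * H, 0.4 * H),
             length=0.45 * H),
    ]
    for side, sgn in (("l", 1.0), ("r", -1.0)):
        segments += [
            dict(name=f"upper_arm_{side}", parent="torso",
                 joint_origin=[0, sgn * 0.13 * H, 0.32 * H], dofs=[],
                 mass=MASS_FRACTIONS["upper_arm"] * mass, com=[0, 0, -0.436 * lua],
                 inertia=_rod_inertia(MASS_FRACTIONS["upper_arm"] * mass, lua), length=lua),
            dict(name=f"forearm_{side}", parent=f"upper_arm_{side}",
                 joint_origin=[0, 0, -lua], dofs=[],
                 mass=MASS_FRACTIONS["forearm"] * mass, com=[0, 0, -0.43 * lfa],
                 inertia=_rod_inertia(MASS_FRACTIONS["forearm"] * mass, lfa), length=lfa),
            dict(name=f"thigh_{side}", parent="pelvis",
                 joint_origin=[0, sgn * hw, -0.03 * H],
                 dofs=[dict(name=f"hip_flexion_{side}", axis=[0, 1, 0], joint_class="hip_fe"),
                       dict(name=f"hip_adduction_{side}", axis=[1, 0, 0], joint_class="hip_aa")],
                 mass=MASS_FRACTIONS["thigh"] * mass, com=[0, 0, -0.433 * lt],
                 inertia=_rod_inertia(MASS_FRACTIONS["thigh"] * mass, lt), length=lt),
            dict(name=f"shank_{side}", parent=f"thigh_{side}", joint_origin=[0, 0, -lt],
                 dofs=[dict(name=f"knee_{side}", axis=[0, 1, 0], joint_class="knee")],
                 mass=MASS_FRACTIONS["shank"] * mass, com=[0, 0, -0.433 * ls],
                 inertia=_rod_inertia(MASS_FRACTIONS["shank"] * mass, ls), length=ls),
            dict(name=f"foot_{side}", parent=f"shank_{side}", joint_origin=[0, 0, -ls],
                 dofs=[dict(name=f"ankle_{side}", axis=[0, 1, 0], joint_class="ankle")],
                 mass=MASS_FRACTIONS["foot"] * mass, com=[0.2 * lf, 0, -0.5 * ha],
                 inertia=_box_inertia(MASS_FRACTIONS["foot"] * mass, lf, 0.35 * lf, ha),
                 length=lf),
        ]

    # six-point sole contour (hexagon around the heel-toe segment), foot frame
    xh, xt = -0.25 * lf, 0.75 * lf
    w1, w2 = 0.022 * H, 0.030 * H
    xm = 0.5 * (xh + xt)
    margin = 0.02 * lf
    contour = [
        [xh - margin, -w1, -ha], [xh - margin, w1, -ha], [xm, w2, -ha],
        [xt + margin, w1, -ha], [xt + margin, -w1, -ha], [xm, -w2, -ha],
    ]
    feet = [
        dict(side="left", segment="foot_l", heel=[xh, 0, -ha], toe=[xt, 0, -ha], contour=contour),
        dict(side="right", segment="foot_r", heel=[xh, 0, -ha], toe=[xt, 0, -ha], contour=contour),
    ]
    return dict(gravity=[0.0, 0.0, -9.81], origin_segment="pelvis", segments=segments, feet=feet)


# ---------------------------------------------------------------------------
# gait synthesis
# ---------------------------------------------------------------------------

@dataclass
class GaitParams:
    """Walking-condition parameters for the synthetic gait generator.

    ``double_support_fraction`` is the total fraction of the cycle spent with
    both feet loaded (two double-support windows per cycle).  ``amplitudes``
    holds the task-space amplitude map (m): pelvis vertical bob, swing foot
    clearance, lateral foot placement, and the heel/toe limits of the designed
    center-of-pressure roll under each stance foot (relative to the ankle).
    """

    period: float = 1.15  # s per gait cycle (two steps)
    double_support_fraction: float = 0.24
    step_length: float = 0.35  # m between successive foot placements
    cadence_noise: float = 0.0  # fractional jitter of the period
    seed: int = 0
    dt: float = 0.01  # s sample spacing
    n_cycles: float = 1.0
    amplitudes: dict = field(default_factory=lambda: dict(
        bob=0.02, clearance=0.06, foot_lateral=0.09, cop_inset=0.008))
    n_harmonics: int = 24

    def __post_init__(self):
        if not (0.0 < self.double_support_fraction < 0.5):
            raise ValueError("double_support_fraction must be in (0, 0.5)")
        if self.period <= 0:
            raise ValueError("period must be > 0")


def _smoothstep5(u: np.ndarray) -> np.ndarray:
    """Quintic smoothstep: C2-continuous 0->1 ramp."""
    u = np.clip(u, 0.0, 1.0)
    return u**3 * (10.0 - 15.0 * u + 6.0 * u**2)


def _swing_bump(u: np.ndarray) -> np.ndarray:
    """C2 bump, 0 at both ends, 1 at u = 1/2."""
    u = np.clip(u, 0.0, 1.0)
    return 64.0 * u**3 * (1.0 - u) ** 3


class _FourierChannel:
    """Truncated Fourier series (plus optional linear trend) of one channel."""

    def __init__(self, values: np.ndarray, period: float, n_harmonics: int, slope: float = 0.0):
        n = len(values)
        coeffs = np.fft.rfft(values) / n
        k_max = min(n_harmonics, len(coeffs) - 1)
        self.c0 = float(coeffs[0].real)
        self.a = 2.0 * coeffs[1 : k_max + 1].real
        self.b = -2.0 * coeffs[1 : k_max + 1].imag
        self.k = np.arange(1, k_max + 1)
        self.w = 2.0 * math.pi / period
        self.slope = slope

    def eval(self, t: float) -> tuple[float, float, float]:
        kw = self.k * self.w
        c, s = np.cos(kw * t), np.sin(kw * t)
        val = self.c0 + self.slope * t + float(self.a @ c + self.b @ s)
        vel = self.slope + float(kw @ (self.b * c - self.a * s))
        acc = -float((kw**2) @ (self.a * c + self.b * s))
        return val, vel, acc


def _leg_ik(p: np.ndarray, lt: float, ls: float) -> tuple[float, float, float]:
    """(hip flexion, hip adduction, knee) from the hip-to-ankle vector ``p``.

    Hip rotation is Ry(fe) @ Rx(aa); knee flexion k >= 0 swings the shank
    backward.  Out-of-reach targets clamp to a straight knee.
    """
    d2 = float(p @ p)
    ck = (d2 - lt * lt - ls * ls) / (2.0 * lt * ls)
    k = math.acos(min(max(ck, -1.0), 1.0))
    qx, qz = -ls * math.sin(k), -(lt + ls * math.cos(k))
    aa = math.asin(min(max(p[1] / abs(qz), -1.0), 1.0))
    ux, uz = qx, math.cos(aa) * qz
    fe = math.atan2(uz, ux) - math.atan2(p[2], p[0])
    fe = (fe + math.pi) % (2.0 * math.pi) - math.pi
    return fe, aa, k


def generate_gait(model: BodyModel, params: GaitParams | None = None,
                  max_iter: int = 10, pierce_tol: float = 3e-3) -> list[MotionSample]:
    """Synthesize a walking trajectory for ``model`` (a generate_model body).

    Foot placements and a target ground-pierce trajectory of the whole-body
    inertial wrench are designed first: the pierce point (the zero-moment
    point) rolls heel-to-toe under each stance foot and blends between feet
    across the double-support windows.  The pelvis trajectory realising that
    target cannot be written down open-loop — at walking frequency the pierce
    point of a swaying body moves opposite to, and larger than, the sway — so
    it is found by fixed-point iteration: evaluate the true pierce point
    through the full dynamics pipeline, correct the pelvis harmonics with the
    linear-inverted-pendulum transfer 1/(1 - z (k w)^2 / g) per harmonic, and
    repeat until the pierce tracks the target to ``pierce_tol``.

    Joint angles follow by per-leg inverse kinematics, and every channel is a
    truncated Fourier series, so velocities/accelerations are analytic and
    exactly consistent.  Deterministic for a fixed seed; the seed perturbs the
    cycle period (cadence noise) and the starting phase.
    """
    params = params or GaitParams()
    rng = np.random.default_rng(params.seed)
    T = params.period * (1.0 + params.cadence_noise * float(np.clip(rng.standard_normal(), -2, 2)))
    t0 = float(rng.uniform(0.0, T))

    lt = float(np.linalg.norm(model.segments["shank_l"].joint_origin))
    ls = float(np.linalg.norm(model.segments["foot_l"].joint_origin))
    hips = {"left": model.segments["thigh_l"].joint_origin,
            "right": model.segments["thigh_r"].joint_origin}
    ha = -float(model.feet["left"].heel[2])

    amp = params.amplitudes
    step = params.step_length
    dsf = params.double_support_fraction
    fl = amp["foot_lateral"]
    delta = amp["cop_inset"]
    v = 2.0 * step / T  # forward speed
    g = abs(float(model.gravity[2]))

    # contour extremes along the foot axis (relative to the ankle)
    contour_x = model.feet["left"].contour[:, 0]
    heel_tip, toe_tip = float(contour_x.min()), float(contour_x.max())
    tip_gap = step - (toe_tip - heel_tip)  # trailing toe tip -> leading heel tip
    if tip_gap <= 4.0 * delta:
        raise ValueError("step_length too short: stance feet overlap along the travel axis")

    # The designed pierce (zero-moment) trajectory rolls heel->toe under each
    # stance foot and crosses the inter-tip gap during the weight-transfer
    # window.  The classifier calls the sample double support only while the
    # pierce is outside both contours, i.e. strictly between the tips, so the
    # window W is sized to make that sub-interval equal the requested
    # double-support fraction.
    frac_between = tip_gap / (tip_gap + 2.0 * delta)
    W = (dsf / 2.0) / frac_between  # transition window, fraction of cycle
    if W >= 0.5:
        raise ValueError("double_support_fraction unreachable for this geometry")
    stance_T = (0.5 + W) * T  # each foot is loaded for its stance + both transitions
    c_lead = 0.5 * v * stance_T  # symmetric fore/aft ankle excursion in stance
    leg = lt + ls
    # pelvis height leaves knee-flexion slack so the pelvis corrections below
    # never drive the legs into the straight-knee reach limit
    vert_ds = math.sqrt(max((0.93 * leg) ** 2 - c_lead**2, 0.25 * leg**2))
    z_pelvis_mid = vert_ds + ha - float(hips["left"][2]) + amp["bob"] / 2.0

    def rel_ankle(tau: float, side: str) -> np.ndarray:
        """Ankle position minus the forward drift (v * tau), world frame."""
        y = fl * (1.0 if side == "left" else -1.0)
        shift = 0.0 if side == "left" else 0.5 * T
        ph = (tau - shift) % T  # time since this foot's heel strike
        x_stance = v * (tau - ph) + c_lead
        if ph <= stance_T:
            x, z = x_stance, ha
        else:
            u = (ph - stance_T) / (T - stance_T)
            x = x_stance + 2.0 * step * float(_smoothstep5(np.array(u)))
            z = ha + amp["clearance"] * float(_swing_bump(np.array(u)))
        return np.array([x - v * tau, y, z])

    def desired_pierce(tau: float) -> np.ndarray:
        """Designed pierce point minus the forward drift (x, y on the ground)."""
        u = (tau % T) / T
        # lead = foot that struck at the start of the current half-cycle
        lead, lag = ("left", "right") if u < 0.5 else ("right", "left")
        uh = u % 0.5  # phase within the half-cycle
        y_lead = fl * (1.0 if lead == "left" else -1.0)
        x_lead_ankle = v * (tau - uh * T) + c_lead  # lead ankle (absolute)
        x_lag_ankle = x_lead_ankle - step
        if uh < W:  # weight transfer: trailing toe tip -> leading heel tip
            s = uh / W
            x = (x_lag_ankle + toe_tip - delta) + s * (tip_gap + 2.0 * delta)
            y = -y_lead + 2.0 * y_lead * s
        else:  # single support: heel->toe COP roll under the lead foot
            s = (uh - W) / (0.5 - W)
            x = x_lead_ankle + (heel_tip + delta) + s * ((toe_tip - delta) - (heel_tip + delta))
            y = y_lead
        return np.array([x - v * tau, y])

    # --- fixed-point search for the pelvis trajectory ----------------------
    n_fit = 256
    taus = np.arange(n_fit) * (T / n_fit)
    nh = params.n_harmonics
    px = np.zeros(n_fit)  # periodic pelvis x (drift removed)
    py = np.zeros(n_fit)
    pz = z_pelvis_mid - (amp["bob"] / 2.0) * (1.0 + np.cos(4.0 * math.pi * taus / T))
    p_des = np.array([desired_pierce(tau) for tau in taus])
    # round the piecewise-linear kinks (circular Hann smoothing, ~2% of the
    # cycle) so the target stays trackable by a truncated harmonic pelvis
    kern = np.hanning(7)[1:-1]
    kern /= kern.sum()
    for c in range(2):  # drift-removed columns are periodic, wrap circularly
        ext = np.concatenate([p_des[-2:, c], p_des[:, c], p_des[:2, c]])
        p_des[:, c] = np.convolve(ext, kern, mode="same")[2:-2]
    ankles = {side: np.array([rel_ankle(tau, side) for tau in taus])
              for side in ("left", "right")}

    def build_channels(px_vals, py_vals):
        base_f = {"x": _FourierChannel(px_vals, T, nh, slope=v),
                  "y": _FourierChannel(py_vals, T, nh),
                  "z": _FourierChannel(pz, T, nh)}
        # IK in drift-removed coordinates (ankle targets are drift-removed too)
        # against the truncated-Fourier pelvis so feet stay consistent
        prel = np.array([[base_f[c].eval(tau)[0] - (v * tau if c == "x" else 0.0)
                          for c in ("x", "y", "z")] for tau in taus])
        chan = {name: np.empty(n_fit) for name in model.dof_names}
        for i, tau in enumerate(taus):
            for side, sfx in (("left", "l"), ("right", "r")):
                p = ankles[side][i] - (prel[i] + hips[side])
                fe, aa, k = _leg_ik(p, lt, ls)
                chan[f"hip_flexion_{sfx}"][i] = fe
                chan[f"hip_adduction_{sfx}"][i] = aa
                chan[f"knee_{sfx}"][i] = k
                chan[f"ankle_{sfx}"][i] = -(fe + k)
        joints = [_FourierChannel(chan[name], T, nh) for name in model.dof_names]
        return base_f, joints

    def sample_at(base_f, joints, tau, t=None) -> MotionSample:
        th, thd, thdd = np.empty(model.n_dofs), np.empty(model.n_dofs), np.empty(model.n_dofs)
        for j, f in enumerate(joints):
            th[j], thd[j], thdd[j] = f.eval(tau)
        pos, vel, acc = np.empty(3), np.empty(3), np.empty(3)
        for ax, key in enumerate(("x", "y", "z")):
            pos[ax], vel[ax], acc[ax] = base_f[key].eval(tau)
        return MotionSample(t=tau if t is None else t, base_position=pos,
                            base_orientation=np.eye(3), theta=th, theta_dot=thd,
                            theta_ddot=thdd, base_lin_vel=vel, base_lin_acc=acc)

    def pierce_of(base_f, joints, tau) -> np.ndarray:
        kin = forward_kinematics(model, sample_at(base_f, joints, tau))
        w = aggregate_inertial_wrench(model, kin)
        caw = central_axis_reduction(w)
        P0, F = caw.point, caw.force
        s = -P0[2] / F[2]
        return (P0 + s * F)[:2] - np.array([v * tau, 0.0])

    # pierce response to a pelvis harmonic k: H = 1 + z (k w)^2 / g (in phase,
    # amplified -- the zero-moment point relation p = x - (z/g) x''), so the
    # per-harmonic Newton preconditioner is 1/H
    z_com = z_pelvis_mid + 0.1 * leg  # rough whole-body COM height
    k_arr = np.arange(n_fit // 2 + 1)
    den = 1.0 + z_com * (k_arr * 2.0 * math.pi / T) ** 2 / g
    gain = np.where(k_arr <= nh, 1.0 / den, 0.0)

    # safeguarded fixed-point iteration: keep the best pelvis found, cap the
    # correction per step (large steps leave the linear-response regime),
    # halve the step (restarting from the best) on regression
    step_cap = 0.04  # m
    history: list[float] = []
    best = None  # (err_max, px, py, err_field, base_f, joints)
    mu = 1.0
    for _ in range(max_iter):
        base_f, joints = build_channels(px, py)
        pierce = np.array([pierce_of(base_f, joints, tau) for tau in taus])
        err = p_des - pierce
        e = float(np.max(np.abs(err)))
        history.append(e)
        if best is None or e < best[0]:
            best = (e, px, py, err, base_f, joints)
            mu = min(1.25 * mu, 1.0)
        else:
            mu *= 0.5
        if best[0] < pierce_tol:
            break
        _, bpx, bpy, berr, _, _ = best
        dx = mu * np.fft.irfft(np.fft.rfft(berr[:, 0]) * gain, n=n_fit)
        dy = mu * np.fft.irfft(np.fft.rfft(berr[:, 1]) * gain, n=n_fit)
        for d in (dx, dy):
            mx = float(np.max(np.abs(d)))
            if mx > step_cap:
                d *= step_cap / mx
        px = bpx + dx
        py = bpy + dy
    _, _, _, best_err, base_f, joints = best
    generate_gait.last_pierce_errors = history  # introspection/diagnostics
    generate_gait.last_error_field = best_err
    generate_gait.last_target = p_des
    generate_gait.last_taus = taus

    # --- emit the sampled trajectory ---------------------------------------
    n_samples = int(round(params.n_cycles * T / params.dt)) + 1
    return [sample_at(base_f, joints, i * params.dt + t0, t=i * params.dt)
            for i in range(n_samples)]


# ---------------------------------------------------------------------------
# ground truth
# ---------------------------------------------------------------------------

@dataclass
class TruthRecord:
    """Reference contact state for one sample (plays the role of force-plate data)."""

    t: float
    phase: str
    a: float = np.nan
    b: float = np.nan
    k: float = np.nan
    f_left: np.ndarray = field(default_factory=lambda: np.zeros(3))
    f_right: np.ndarray = field(default_factory=lambda: np.zeros(3))
    cop_left: np.ndarray | None = None
    cop_right: np.ndarray | None = None
    feasible: bool = True


def generate_truth(model: BodyModel, samples, mode: str = "arbitrary",
                   factors: EnergyModel | None = None, grid_step: float | None = None,
                   seed: int = 0, k_grid_step: float = 2e-4) -> list[TruthRecord]:
    """Ground-truth contact forces for a motion trajectory.

    mode "arbitrary": smooth planted COP/split profiles a(t), k(t) inside the
    feasible region, forces via the decoupled solve — balance holds by
    construction.  mode "energy_minimal": (a, k) located by an exhaustive 2-D
    grid search of the energy surface (direct evaluation over a dense k grid,
    no closed-form minimisation), enabling recovery tests of the optimizer.

    Single-support samples carry the exact closed-form truth.  Samples with
    no feasible COP pairing are flagged ``feasible=False`` and carry no
    estimate.
    """
    if mode not in ("arbitrary", "energy_minimal"):
        raise ValueError(f"unknown truth mode {mode!r}")
    em = factors or EnergyModel.default()
    rng = np.random.default_rng(seed)
    ph_a, ph_k = rng.uniform(0.0, 2.0 * math.pi, size=2)

    out: list[TruthRecord] = []
    for s in samples:
        try:
            kin = forward_kinematics(model, s)
            w = aggregate_inertial_wrench(model, kin)
            caw = central_axis_reduction(w)
            state = classify_support(caw, kin)
        except (PureCoupleError, NoPiercePointError) as e:
            out.append(TruthRecord(t=s.t, phase="failed", feasible=False))
            continue

        if state.phase != DOUBLE:
            sol = single_support_solution(w, caw, state, kin)
            out.append(TruthRecord(t=s.t, phase=sol.phase, a=sol.a, b=sol.b, k=sol.k,
                                   f_left=sol.f_left, f_right=sol.f_right,
                                   cop_left=sol.cop_left, cop_right=sol.cop_right))
            continue

        left, right = kin.feet["left"], kin.feet["right"]
        A, B, C, D = left.heel, left.toe, right.heel, right.toe
        try:
            if mode == "arbitrary":
                rngf = feasible_a_range(A=A, B=B, C=C, D=D, P=caw.point, f_dir=caw.direction,
                                        grid_step=grid_step or (np.linalg.norm(B - A) / 200.0))
                frac = 0.5 + 0.35 * math.sin(2.0 * math.pi * 0.9 * s.t + ph_a)
                a = rngf.a1 + frac * (rngf.a2 - rngf.a1)
                k = 0.5 + 0.3 * math.sin(2.0 * math.pi * 1.3 * s.t + ph_k)
                geom = contact_geometry(a, A=A, B=B, C=C, D=D, P=caw.point, f_dir=caw.direction)
                frame = ddcs_frame(geom)
                sys = solve_decoupled(frame, w)
                _, _, fl_w, fr_w = split_axial(sys, k)
                out.append(TruthRecord(t=s.t, phase=DOUBLE, a=a, b=geom.b, k=k,
                                       f_left=fl_w, f_right=fr_w,
                                       cop_left=geom.M, cop_right=geom.N))
            else:
                problem = build_problem(model, kin, w, caw, grid_step=grid_step, t=s.t)
                f = em.factor_vector(list(model.dof_classes))
                k_coarse = np.arange(-200.0, 200.0 + 0.25, 0.5)
                best = (np.inf, 0, 0.0)
                for i in range(problem.u.shape[0]):
                    # nested direct grid search in k: coarse bracket, then
                    # refine at k_grid_step resolution (no closed forms)
                    def E_of(ks):
                        Tk = problem.u[i][None, :] + ks[:, None] * problem.v[i][None, :]
                        return (Tk * Tk) @ f
                    Ec = E_of(k_coarse)
                    kc = float(k_coarse[int(np.argmin(Ec))])
                    k_fine = np.arange(kc - 0.5, kc + 0.5 + k_grid_step / 2, k_grid_step)
                    Ef = E_of(k_fine)
                    j = int(np.argmin(Ef))
                    if Ef[j] < best[0]:
                        best = (float(Ef[j]), i, float(k_fine[j]))
                _, i, k = best
                fl_w = problem.fl0_w[i] + k * problem.g_w[i]
                fr_w = problem.fr0_w[i] - k * problem.g_w[i]
                out.append(TruthRecord(t=s.t, phase=DOUBLE, a=float(problem.a[i]),
                                       b=float(problem.b[i]), k=k,
                                       f_left=fl_w, f_right=fr_w,
                                       cop_left=problem.M[i], cop_right=problem.N[i]))
        except (NoFeasibleCopError, EstimationError, DegenerateGeometryError):
            out.append(TruthRecord(t=s.t, phase=DOUBLE, feasible=False))
    return out
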