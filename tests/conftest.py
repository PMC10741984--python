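"""Shared fixtures: anthropometric model, cached synthetic gait, estimates.

Gait synthesis and trajectory estimation are the expensive steps, so they are
memoised per seed and shared across the whole session.
"""

from __future__ import annotations

import functools

import numpy as np
import pytest

import gaitwrench as gw
from gaitwrench.energy_optimizer import EnergyModel, estimate_trajectory
from gaitwrench.synthetic_gait import GaitParams, generate_gait, generate_model, generate_truth


@functools.lru_cache(maxsize=None)
def default_model() -> gw.BodyModel:
    return gw.load_model(generate_model(1.75, 70.0))


@functools.lru_cache(maxsize=None)
def gait_samples(seed: int) -> tuple:
    return tuple(generate_gait(default_model(), GaitParams(seed=seed)))


@functools.lru_cache(maxsize=None)
def gait_solutions(seed: int) -> tuple:
    return tuple(estimate_trajectory(default_model(), gait_samples(seed)))


@functools.lru_cache(maxsize=None)
def gait_truth(seed: int, mode: str) -> tuple:
    return tuple(generate_truth(default_model(), gait_samples(seed), mode=mode, seed=seed))


def pipeline(model: gw.BodyModel, sample: gw.MotionSample):
    """(kinematics, wrench, central-axis wrench, support state) for a sample."""
    kin = gw.forward_kinematics(model, sample)
    w = gw.aggregate_inertial_wrench(model, kin)
    caw = gw.central_axis_reduction(w)
    state = gw.classify_support(caw, kin)
    return kin, w, caw, state


def double_support_frames(seed: int):
    """(sample, kin, wrench, caw, state) for each frame classified double."""
    model = default_model()
    out = []
    for s in gait_samples(seed):
        kin, w, caw, state = pipeline(model, s)
        if state.phase == gw.DOUBLE:
            out.append((s, kin, w, caw, state))
    return out


def full_pipeline_energy(model, kin, w, caw, a, k, em):
    """E(a, k) evaluated through the complete public path (geometry -> DDCS
    solve -> axial split -> inverse dynamics -> weighted energy)."""
    from gaitwrench.ddcs_solver import contact_geometry, ddcs_frame, solve_decoupled, split_axial
    from gaitwrench.energy_optimizer import energy
    from gaitwrench.inverse_dynamics import Contact, joint_moments

    left, right = kin.feet["left"], kin.feet["right"]
    geom = contact_geometry(a, A=left.heel, B=left.toe, C=right.heel, D=right.toe,
                            P=caw.point, f_dir=caw.direction)
    frame = ddcs_frame(geom)
    sys = solve_decoupled(frame, w)
    _, _, fl_w, fr_w = split_axial(sys, k)
    T = joint_moments(model, kin, (
        Contact(model.feet["left"].segment, fl_w, geom.M),
        Contact(model.feet["right"].segment, fr_w, geom.N),
    ))
    return energy(T, em)


def dummy_feet(segment: str = "base", lf: float = 0.25) -> list[dict]:
    """Minimal valid pair of feet (attached to one segment) for toy models."""
    contour = [[-0.05, -0.05, 0], [-0.05, 0.05, 0], [0.1, 0.06, 0],
               [lf + 0.05, 0.05, 0], [lf + 0.05, -0.05, 0], [0.1, -0.06, 0]]
    return [
        dict(side="left", segment=segment, heel=[0, 0, 0], toe=[lf, 0, 0], contour=contour),
        dict(side="right", segment=segment, heel=[0, 0.4, 0], toe=[lf, 0.4, 0],
             contour=[[x, y + 0.4, z] for x, y, z in contour]),
    ]


def toy_model(segments: list[dict], feet: list[dict] | None = None, **kw) -> gw.BodyModel:
    cfg = dict(segments=segments, feet=feet or dummy_feet(segments[0]["name"]), **kw)
    return gw.load_model(cfg)


@pytest.fixture(scope="session")
def model():
    return default_model()


@pytest.fixture(scope="session")
def walk1():
    return gait_samples(1)


@pytest.fixture(scope="session")
def sols1():
    return gait_solutions(1)


@pytest.fixture(scope="session")
def em_default():
    return EnergyModel.default()


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
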