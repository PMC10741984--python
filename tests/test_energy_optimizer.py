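"""Energy objective, feasible COP range, traversal + closed-form minimisation."""

import numpy as np
import pytest

import gaitwrench as gw
from gaitwrench.energy_optimizer import (EnergyModel, MissingFactorError, NoFeasibleCopError,
                                         build_problem, energy, energy_profile,
                                         estimate_trajectory, feasible_a_range, optimize_sample,
                                         solve_with_factors)
from gaitwrench.inverse_dynamics import JointMomentResult
from gaitwrench.motion_io import solutions_to_dataframe

from conftest import (default_model, double_support_frames, full_pipeline_energy,
                      gait_samples, pipeline)

from test_ddcs_solver import symmetric_stance


class TestEnergy:
    def test_weighted_sum_of_squares(self):
        res = JointMomentResult(moments=np.array([1.0, 1.0, 1.0]),
                                dof_names=["haa", "kne", "ank"],
                                joint_classes=["hip_aa", "knee", "ankle"])
        em = EnergyModel.from_q(q0=1.0, q1=2.1, q2=0.1)
        assert energy(res, em) == pytest.approx(3.2, abs=1e-12)

    def test_zero_moments_zero_energy(self):
        res = JointMomentResult(np.zeros(4), ["a"] * 4, ["knee"] * 4)
        assert energy(res, EnergyModel.default()) == 0.0

    def test_quadratic_homogeneity(self):
        res = JointMomentResult(np.array([2.0, -3.0]), ["a", "b"], ["knee", "ankle"])
        res2 = JointMomentResult(2 * res.moments, res.dof_names, res.joint_classes)
        em = EnergyModel.default()
        assert energy(res2, em) == pytest.approx(4 * energy(res, em), rel=1e-12)

    def test_missing_class_raises(self):
        res = JointMomentResult(np.ones(1), ["j"], ["elbow"])
        with pytest.raises(MissingFactorError):
            energy(res, EnergyModel.default())

    def test_nonpositive_factor_rejected(self):
        with pytest.raises(ValueError):
            EnergyModel.from_q(q1=0.0)


class TestFeasibleRange:
    def test_symmetric_stance_full_interval(self):
        g = symmetric_stance(lf=0.25)
        rng_f = feasible_a_range(**g, grid_step=0.25 / 100)
        assert rng_f.a1 == pytest.approx(0.0)
        assert rng_f.a2 == pytest.approx(0.25)
        assert rng_f.mask.all()

    def test_coarse_bounds_match_fine_scan(self, model):
        frames = double_support_frames(1)
        for _, kin, w, caw, _ in frames[::9]:
            left, right = kin.feet["left"], kin.feet["right"]
            args = dict(A=left.heel, B=left.toe, C=right.heel, D=right.toe,
                        P=caw.point, f_dir=caw.direction)
            lf = model.feet["left"].lf
            coarse = feasible_a_range(**args, grid_step=lf / 50)
            fine = feasible_a_range(**args, grid_step=lf / 500)
            assert abs(coarse.a1 - fine.a1) <= lf / 50 + 1e-12
            assert abs(coarse.a2 - fine.a2) <= lf / 50 + 1e-12

    def test_degenerate_geometry_everywhere_raises(self):
        g = symmetric_stance()
        g["C"] = np.array([0.1, -0.1, 0.0])
        g["D"] = np.array([0.1, -0.1, 0.25])  # CD parallel to the force axis
        with pytest.raises(NoFeasibleCopError):
            feasible_a_range(**g, grid_step=0.01)


class TestOptimizeSample:
    def test_quadratic_fit_matches_probe_evaluations(self, model, em_default):
        """E(k) from the fitted coefficients agrees with direct full-pipeline
        evaluations at off-grid probe k values."""
        s, kin, w, caw, state = double_support_frames(1)[4]
        problem = build_problem(model, kin, w, caw, state=state)
        prof = energy_profile(problem, em_default)
        i = len(problem.a) // 2
        for k in np.linspace(-1.0, 2.0, 10):
            e_fit = prof.e0[i] * k * k + prof.e1[i] * k + prof.e2[i]
            e_full = full_pipeline_energy(model, kin, w, caw, problem.a[i], k, em_default)
            assert e_fit == pytest.approx(e_full, rel=1e-8)

    def test_matches_coarse_exhaustive_search(self, model, em_default):
        """Traversal + closed-form k* equals a brute-force (a, k) grid scan
        evaluated entirely through the full public pipeline (two-stage k
        grid: 0.02 bracket, then 2e-4 refinement)."""
        lf = model.feet["left"].lf
        for s, kin, w, caw, state in double_support_frames(1)[5:6]:
            sol = optimize_sample(model, s, em_default, grid_step=lf / 20)
            problem = build_problem(model, kin, w, caw, grid_step=lf / 20, state=state)
            best = (np.inf, None, None)
            for i, a in enumerate(problem.a):
                es = {k: full_pipeline_energy(model, kin, w, caw, a, k, em_default)
                      for k in np.arange(-8.0, 8.0, 0.05)}
                kc = min(es, key=es.get)
                for k in np.arange(kc - 0.075, kc + 0.075, 2e-4):
                    e = full_pipeline_energy(model, kin, w, caw, a, k, em_default)
                    if e < best[0]:
                        best = (e, a, k)
            assert sol.energy == pytest.approx(best[0], rel=1e-5)
            assert abs(sol.a - best[1]) <= lf / 20 + 1e-12
            assert abs(sol.k - best[2]) <= 2e-4 + 1e-9

    def test_single_support_short_circuits(self, model, em_default, walk1):
        for s in walk1:
            kin, w, caw, state = pipeline(model, s)
            if state.phase != gw.DOUBLE:
                sol = optimize_sample(model, s, em_default)
                ref = gw.single_support_solution(w, caw, state, kin)
                assert sol.phase == ref.phase
                np.testing.assert_array_equal(sol.f_left, ref.f_left)
                np.testing.assert_array_equal(sol.f_right, ref.f_right)
                break

    def test_halving_grid_step_never_increases_energy(self, model, em_default):
        s, kin, w, caw, state = double_support_frames(1)[10]
        lf = model.feet["left"].lf
        e_coarse = optimize_sample(model, s, em_default, grid_step=lf / 50).energy
        e_fine = optimize_sample(model, s, em_default, grid_step=lf / 100).energy
        assert e_fine <= e_coarse + 1e-9 * abs(e_coarse)

    def test_axial_split_sums_to_total(self, sols1):
        for sol in sols1:
            if sol.phase == gw.DOUBLE:
                total = sol.f_left_ddcs[0] + sol.f_right_ddcs[0]
                assert sol.f_left_ddcs[0] == pytest.approx(sol.k * total, abs=1e-9 * max(1, abs(total)))

    def test_clamp_k_flag(self, model, em_default):
        # find a frame whose unconstrained split leaves [0, 1]
        for s, *_ in double_support_frames(1):
            sol = optimize_sample(model, s, em_default)
            if not (0.0 <= sol.k <= 1.0):
                clamped = optimize_sample(model, s, em_default, clamp_k=True)
                assert 0.0 <= clamped.k <= 1.0
                break


class TestEstimateTrajectory:
    def test_full_gait_labels_every_sample(self, sols1, walk1):
        assert len(sols1) == len(walk1)
        assert all(s.phase in (gw.DOUBLE, gw.LEFT_SINGLE, gw.RIGHT_SINGLE) for s in sols1)
        times = [s.t for s in sols1]
        assert times == sorted(times)

    def test_empty_input_empty_output(self, model, em_default):
        assert estimate_trajectory(model, [], em_default) == []

    def test_deterministic_rerun(self, model, em_default):
        samples = gait_samples(1)[30:40]
        df1 = solutions_to_dataframe(estimate_trajectory(model, samples, em_default))
        df2 = solutions_to_dataframe(estimate_trajectory(model, samples, em_default))
        assert df1.equals(df2)
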