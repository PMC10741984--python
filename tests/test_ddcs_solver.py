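"""COP coupling, DDCS construction, the decoupled solve, and rank analysis."""

import numpy as np
import pytest
import sympy

import gaitwrench as gw
from gaitwrench.ddcs_solver import (DegenerateGeometryError, balance_matrix, contact_geometry,
                                    coupled_b, ddcs_frame, rank_analysis, rank_invariance,
                                    solve_decoupled, split_axial, DDCSFrame)
from gaitwrench.inertial_wrench import Wrench
from gaitwrench.body_model import rotation_about_axis

from conftest import default_model, double_support_frames


def symmetric_stance(lf=0.25, half_width=0.1, px=0.125):
    """Parallel feet mirrored across y = 0; vertical force piercing the
    midline at x = px.  Coplanarity forces M, N and the pierce point to be
    collinear, so b(a) = 2 px - a."""
    return dict(A=np.array([0.0, half_width, 0.0]), B=np.array([lf, half_width, 0.0]),
                C=np.array([0.0, -half_width, 0.0]), D=np.array([lf, -half_width, 0.0]),
                P=np.array([px, 0.0, 1.0]), f_dir=np.array([0.0, 0.0, -1.0]))


def random_geometry(rng):
    """A non-degenerate double-support geometry with a downward-ish axis."""
    A = np.array([rng.uniform(-0.1, 0.1), rng.uniform(0.05, 0.25), 0.0])
    B = A + np.array([rng.uniform(0.2, 0.3), rng.uniform(-0.08, 0.08), 0.0])
    C = np.array([rng.uniform(-0.1, 0.1), rng.uniform(-0.25, -0.05), 0.0])
    D = C + np.array([rng.uniform(0.2, 0.3), rng.uniform(-0.08, 0.08), 0.0])
    P = np.array([rng.uniform(0.0, 0.2), rng.uniform(-0.05, 0.05), rng.uniform(0.8, 1.2)])
    f = np.array([rng.uniform(-0.3, 0.3), rng.uniform(-0.3, 0.3), -1.0])
    return dict(A=A, B=B, C=C, D=D, P=P, f_dir=f / np.linalg.norm(f))


class TestCoupledB:
    def test_symmetric_stance_mirrors_a(self):
        # axis through the stance centre: the mid-foot COPs mirror each other
        g = symmetric_stance(px=0.125)
        assert coupled_b(0.125, **g) == pytest.approx(0.125, abs=1e-12)
        # axis through the heels' transverse line: heel maps to heel
        assert coupled_b(0.0, **symmetric_stance(px=0.0)) == pytest.approx(0.0, abs=1e-12)
        # general parallel-feet coupling: M, pierce point, N collinear
        for px in (0.04, 0.11):
            for a in (0.03, 0.2):
                assert coupled_b(a, **symmetric_stance(px=px)) == pytest.approx(2 * px - a, abs=1e-12)

    def test_matches_bisection_root_of_coplanarity(self, rng):
        """b equals the root of the coplanarity residual found by bisection."""
        for _ in range(25):
            g = random_geometry(rng)
            b = coupled_b(0.11, **g)
            M = g["A"] + 0.11 * (g["B"] - g["A"]) / np.linalg.norm(g["B"] - g["A"])
            ucd = (g["D"] - g["C"]) / np.linalg.norm(g["D"] - g["C"])

            def resid(bb):
                N = g["C"] + bb * ucd
                return float(np.cross(M - g["P"], N - g["P"]) @ g["f_dir"])

            lo, hi = -5.0, 5.0
            assert resid(lo) * resid(hi) < 0
            for _ in range(60):
                mid = 0.5 * (lo + hi)
                if resid(lo) * resid(mid) <= 0:
                    hi = mid
                else:
                    lo = mid
            assert b == pytest.approx(0.5 * (lo + hi), abs=1e-8)

    def test_coplanarity_residual_of_coupled_geometry(self, rng):
        for _ in range(25):
            g = random_geometry(rng)
            geom = contact_geometry(0.17, **g)
            assert geom.coplanarity_residual() < 1e-10

    def test_degenerate_direction_raises(self):
        g = symmetric_stance()
        g["C"] = np.array([0.1, -0.1, 0.0])
        g["D"] = np.array([0.1, -0.1, 0.25])  # CD parallel to F
        with pytest.raises(DegenerateGeometryError, match="parallel"):
            coupled_b(0.1, **g)

    def test_b_of_a_is_continuous_on_feasible_grid(self, model):
        frames = double_support_frames(1)
        _, kin, w, caw, _ = frames[len(frames) // 2]
        left, right = kin.feet["left"], kin.feet["right"]
        args = dict(A=left.heel, B=left.toe, C=right.heel, D=right.toe,
                    P=caw.point, f_dir=caw.direction)
        a_fine = np.linspace(0, model.feet["left"].lf, 801)
        b_fine = np.array([coupled_b(a, **args) for a in a_fine])
        slope = np.max(np.abs(np.gradient(b_fine, a_fine)))
        jumps = np.max(np.abs(np.diff(b_fine)))
        assert jumps <= 10.0 * slope * (a_fine[1] - a_fine[0])


class TestDDCSFrame:
    def test_symmetric_stance_has_equal_lever_arms(self):
        g = symmetric_stance(px=0.125)
        geom = contact_geometry(0.125, **g)
        frame = ddcs_frame(geom)
        assert frame.l == pytest.approx(frame.r, abs=1e-12)

    def test_axes_orthonormal_right_handed(self, rng):
        for _ in range(200):
            geom = contact_geometry(rng.uniform(0.02, 0.25), **random_geometry(rng))
            fr = ddcs_frame(geom)
            np.testing.assert_allclose(fr.axes.T @ fr.axes, np.eye(3), atol=1e-12)
            assert np.linalg.det(fr.axes) == pytest.approx(1.0, abs=1e-12)
            # M and N lie on the X-axis through O
            np.testing.assert_allclose(geom.M - fr.origin, fr.l * fr.x_axis, atol=1e-9)
            np.testing.assert_allclose(geom.N - fr.origin, -fr.r * fr.x_axis, atol=1e-9)

    def test_origin_matches_dense_line_search(self, rng):
        """O equals the brute-force minimiser of distance(line MN, axis)."""
        for _ in range(10):
            geom = contact_geometry(0.13, **random_geometry(rng))
            fr = ddcs_frame(geom)
            u = (geom.N - geom.M) / np.linalg.norm(geom.N - geom.M)

            def dist(t):
                q = geom.M + t * u
                w = q - geom.P
                return np.linalg.norm(w - (w @ geom.F_dir) * geom.F_dir)

            ts = np.linspace(-2, 2, 40001)
            t0 = ts[int(np.argmin([dist(t) for t in ts]))]
            ts2 = np.linspace(t0 - 1e-4, t0 + 1e-4, 2001)
            t1 = ts2[int(np.argmin([dist(t) for t in ts2]))]
            assert np.linalg.norm(fr.origin - (geom.M + t1 * u)) < 1e-6

    def test_wrench_transform_matches_to_ddcs(self, rng):
        geom = contact_geometry(0.13, **random_geometry(rng))
        fr = ddcs_frame(geom)
        w = Wrench(rng.normal(size=3), rng.normal(size=3), rng.normal(size=3))
        T = fr.wrench_transform(w.ref_point)
        out = T @ np.concatenate([w.force, w.moment])
        f_d, m_d = fr.to_ddcs(w)
        np.testing.assert_allclose(out[:3], f_d, atol=1e-12)
        np.testing.assert_allclose(out[3:], m_d, atol=1e-12)


class TestDecoupledSolve:
    def _frame(self, l=0.12, r=0.12):
        return DDCSFrame(origin=np.zeros(3), axes=np.eye(3), l=l, r=r)

    def test_symmetric_split_when_moments_vanish(self):
        fr = self._frame()
        w = Wrench(np.array([-10.0, -20.0, -30.0]), np.array([5.0, 0.0, 0.0]), np.zeros(3))
        sys = solve_decoupled(fr, w)
        np.testing.assert_allclose(sys.x, [10.0, 10.0, 15.0, 10.0, 15.0], atol=1e-12)
        assert sys.dropped_MXD == pytest.approx(-5.0)

    def test_matches_pseudo_inverse(self, rng):
        for _ in range(50):
            fr = self._frame(l=rng.uniform(0.01, 0.3), r=rng.uniform(0.01, 0.3))
            w = Wrench(rng.normal(size=3) * 100, rng.normal(size=3) * 30, rng.normal(size=3))
            sys = solve_decoupled(fr, w)
            x_pinv = np.linalg.pinv(sys.A_matrix) @ sys.FD
            np.testing.assert_allclose(sys.x, x_pinv, atol=1e-10 * max(1, np.linalg.norm(sys.FD)))
            resid = sys.A_matrix @ sys.x - sys.FD
            assert np.linalg.norm(resid) <= 1e-10 * max(np.linalg.norm(sys.FD), 1.0)

    def test_zero_rhs_gives_zero(self):
        sys = solve_decoupled(self._frame(), Wrench(np.zeros(3), np.zeros(3), np.zeros(3)))
        np.testing.assert_array_equal(sys.x, np.zeros(5))

    def test_coincident_cops_singular(self):
        with pytest.raises(DegenerateGeometryError, match="singular"):
            solve_decoupled(self._frame(l=0.0, r=0.0), Wrench(np.ones(3), np.ones(3), np.zeros(3)))

    @pytest.mark.parametrize("k", [0.0, 0.5, 1.0, -0.7, 2.3])
    def test_split_preserves_world_balance(self, k, rng):
        geom = contact_geometry(0.13, **random_geometry(rng))
        fr = ddcs_frame(geom)
        w = Wrench(np.array([30.0, -40.0, -600.0]), np.array([12.0, -7.0, 3.0]), np.array([0.1, 0.0, 0.9]))
        sys = solve_decoupled(fr, w)
        fl_d, fr_d, fl_w, fr_w = split_axial(sys, k)
        assert fl_d[0] + fr_d[0] == pytest.approx(sys.x[0], abs=1e-12)
        np.testing.assert_allclose(fl_w + fr_w, -w.force, atol=1e-10 * np.linalg.norm(w.force))

    def test_scene_rotation_covariance(self, rng):
        """Rotating every world input rotates M, N, O and world forces; the
        DDCS components are unchanged."""
        g = random_geometry(rng)
        R = rotation_about_axis(np.array([0.6, 0.64, 0.48]) / np.linalg.norm([0.6, 0.64, 0.48]), 0.9)
        w = Wrench(np.array([20.0, -35.0, -500.0]), np.array([8.0, 2.0, -4.0]), g["P"] + [0, 0, 0.2])
        geom = contact_geometry(0.14, **g)
        sys = solve_decoupled(ddcs_frame(geom), w)
        g2 = {k: (R @ v if k != "f_dir" else R @ v) for k, v in g.items()}
        w2 = Wrench(R @ w.force, R @ w.moment, R @ w.ref_point)
        geom2 = contact_geometry(0.14, **g2)
        sys2 = solve_decoupled(ddcs_frame(geom2), w2)
        assert geom2.b == pytest.approx(geom.b, abs=1e-10)
        np.testing.assert_allclose(geom2.M, R @ geom.M, atol=1e-12)
        np.testing.assert_allclose(sys2.x, sys.x, atol=1e-8)
        _, _, fl_w, _ = split_axial(sys, 0.3)
        _, _, fl_w2, _ = split_axial(sys2, 0.3)
        np.testing.assert_allclose(fl_w2, R @ fl_w, atol=1e-8)


class TestRankAnalysis:
    def test_generic_placement_rank_five(self, rng):
        for _ in range(50):
            a, b, c, d = rng.uniform(0.05, 1.0, 4)
            assert rank_analysis(a, b, c, d) == 5

    def test_zero_scalars_match_symbolic_row_reduction(self):
        got = rank_analysis(0.0, 0.0, 0.0, 0.0)
        M = sympy.Matrix([
            [1, 0, 0, 1, 0, 0], [0, 1, 0, 0, 1, 0], [0, 0, 1, 0, 0, 1],
            [0, 0, 0, 0, 0, 0], [0, 0, 0, 0, 0, 0], [0, 0, 0, 0, 0, 0]])
        assert got == M.rank() == 3

    def test_rotation_preserves_rank(self, rng):
        for _ in range(30):
            r_l, r_r = rng.normal(size=3), rng.normal(size=3)
            R = rotation_about_axis(rng.normal(size=3) / np.linalg.norm(rng.normal(size=3)) if False
                                    else np.array([0, 0, 1.0]), rng.uniform(0, 2 * np.pi))
            ra, rb = rank_invariance(r_l, r_r, R)
            assert ra == rb == 5

    def test_balance_matrix_null_space_is_the_collinear_pair(self, rng):
        """The unresolvable direction is equal-and-opposite forces along the
        line joining the two contact points."""
        r_l, r_r = rng.normal(size=3), rng.normal(size=3)
        A = balance_matrix(r_l, r_r)
        d = (r_l - r_r) / np.linalg.norm(r_l - r_r)
        null = np.concatenate([d, -d])
        np.testing.assert_allclose(A @ null, 0, atol=1e-12)
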