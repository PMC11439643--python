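import numpy as np
import pytest

from canalpose import attitude as att
from conftest import angle_deg


class TestFitPlaneSvd:
    def test_exact_plane(self):
        rng = np.random.default_rng(0)
        xy = rng.normal(size=(30, 2)) * 5
        pts = np.column_stack([xy, np.full(30, 3.0)])
        res = att.fit_plane_svd(pts)
        assert angle_deg(res.normal, [0, 0, 1]) < 1e-9
        assert res.rms_distance < 1e-12
        assert np.all(np.diff(res.singular_values) <= 0)

    def test_rms_matches_definition(self):
        rng = np.random.default_rng(1)
        pts = np.column_stack([rng.normal(size=(50, 2)) * 4,
                               rng.normal(size=50) * 0.3])
        res = att.fit_plane_svd(pts)
        d = (pts - res.centroid) @ res.normal
        assert res.rms_distance == pytest.approx(np.sqrt(np.mean(d**2)))

    def test_agrees_with_covariance_eigenvector_oracle(self):
        rng = np.random.default_rng(2)
        for _ in range(10):
            n_true = rng.normal(size=3)
            n_true /= np.linalg.norm(n_true)
            u = np.cross(n_true, [1.0, 0.3, -0.2])
            u /= np.linalg.norm(u)
            v = np.cross(n_true, u)
            ab = rng.normal(size=(100, 2)) * 10
            pts = ab @ np.stack([u, v]) + rng.normal(size=(100, 3)) * 0.05
            res = att.fit_plane_svd(pts)
            w, V = np.linalg.eigh(np.cov((pts - pts.mean(0)).T))
            oracle = V[:, 0]
            assert angle_deg(res.normal, oracle) < np.degrees(1e-9)

    def test_invariance_under_rigid_motion_and_scaling(self):
        rng = np.random.default_rng(3)
        pts = np.column_stack([rng.normal(size=(40, 2)) * 6,
                               rng.normal(size=40) * 0.1])
        n0 = att.fit_plane_svd(pts).normal
        Q, _ = np.linalg.qr(rng.normal(size=(3, 3)))
        if np.linalg.det(Q) < 0:
            Q[:, 0] = -Q[:, 0]
        moved = 2.5 * (pts @ Q.T) + np.array([1.0, 2.0, 3.0])
        n1 = att.fit_plane_svd(moved).normal
        assert angle_deg(n1, Q @ n0) < 1e-7

    def test_collinear_raises(self):
        pts = np.outer(np.arange(10.0), [1.0, 2.0, 3.0])
        with pytest.raises(ValueError, match="collinear"):
            att.fit_plane_svd(pts)

    def test_too_few_points(self):
        with pytest.raises(ValueError):
            att.fit_plane_svd(np.zeros((2, 3)))


class TestLocalPlaneNormals:
    def _arc(self, n=60):
        t = np.linspace(0, 1.5 * np.pi, n)
        return np.stack([10 * np.cos(t), 10 * np.sin(t), np.zeros_like(t)], axis=1)

    def test_planar_arc_windows_agree_with_global(self):
        pts = self._arc()
        global_n = att.fit_plane_svd(pts).normal
        for n in att.local_plane_normals(pts, window=20):
            assert angle_deg(n, global_n) < 0.1

    def test_window_equal_length_single_global_fit(self):
        pts = self._arc(n=30)
        normals = att.local_plane_normals(pts, window=30)
        assert len(normals) == 1
        assert angle_deg(normals[0], att.fit_plane_svd(pts).normal) < 1e-9

    def test_short_path_falls_back_with_warning(self):
        pts = self._arc(n=10)
        with pytest.warns(UserWarning, match="global"):
            normals = att.local_plane_normals(pts, window=20)
        assert len(normals) == 1

    def test_consecutive_normals_sign_aligned(self):
        rng = np.random.default_rng(4)
        t = np.linspace(0, 1.5 * np.pi, 80)
        pts = np.stack([10 * np.cos(t), 10 * np.sin(t), 0.3 * np.sin(3 * t)], 1)
        pts += rng.normal(size=pts.shape) * 0.05
        normals = att.local_plane_normals(pts, window=15)
        for a, b in zip(normals, normals[1:]):
            assert np.dot(a, b) > 0

    def test_windowed_average_near_global_on_warped_arc(self):
        # gently warped analytic arc: V_avg over windows ~ global normal
        t = np.linspace(0, 1.6 * np.pi, 90)
        pts = np.stack([10 * np.cos(t), 10 * np.sin(t), 0.4 * np.sin(2 * t)], 1)
        normals = att.local_plane_normals(pts, window=30)
        v_avg = att.average_unit_normals(normals)
        assert angle_deg(v_avg, att.fit_plane_svd(pts).normal) < 2.0


class TestOrientNormal:
    def test_lateral_flipped_to_negative_x(self):
        v = np.array([0.98, 0.17, 0.02])
        np.testing.assert_allclose(att.orient_normal(v, "left", "lateral"),
                                   [-0.98, -0.17, -0.02])

    def test_anterior_already_canonical_unchanged(self):
        v = np.array([0.17, -0.56, 0.81])
        np.testing.assert_array_equal(att.orient_normal(v, "left", "anterior"), v)

    def test_lateral_zero_x_falls_back_to_y(self):
        v = np.array([0.0, 0.5, 0.1])
        out = att.orient_normal(v, "right", "lateral")
        np.testing.assert_allclose(out, [0.0, -0.5, -0.1])

    def test_zero_vector_raises(self):
        with pytest.raises(ValueError):
            att.orient_normal(np.zeros(3), "left", "lateral")

    def test_idempotent(self):
        rng = np.random.default_rng(5)
        for canal in ("anterior", "posterior", "lateral"):
            for v in rng.normal(size=(20, 3)):
                once = att.orient_normal(v, "left", canal)
                np.testing.assert_array_equal(
                    att.orient_normal(once, "left", canal), once)


class TestAverageUnitNormals:
    def test_two_orthogonal(self):
        out = att.average_unit_normals([np.array([1.0, 0, 0]),
                                        np.array([0.0, 1, 0])])
        np.testing.assert_allclose(out, [0.70711, 0.70711, 0.0], atol=1e-5)

    def test_identical_vectors(self):
        v = np.array([0.6, 0.8, 0.0])
        np.testing.assert_allclose(att.average_unit_normals([v] * 5), v,
                                   atol=1e-12)

    def test_antipodal_raises(self):
        with pytest.raises(ValueError, match="incoherent"):
            att.average_unit_normals([np.array([1.0, 0, 0]),
                                      np.array([-1.0, 0, 0])])


class TestDirectionAngles:
    def test_axis_vector(self):
        assert att.direction_angles(np.array([1.0, 0, 0])) == (0.0, 90.0, 90.0)

    def test_direction_cosine_identity(self):
        rng = np.random.default_rng(6)
        for v in rng.normal(size=(25, 3)):
            v /= np.linalg.norm(v)
            a, b, c = np.radians(att.direction_angles(v))
            assert np.cos(a)**2 + np.cos(b)**2 + np.cos(c)**2 == pytest.approx(1.0)

    def test_non_unit_rejected(self):
        with pytest.raises(ValueError):
            att.direction_angles(np.array([2.0, 0, 0]))
        with pytest.raises(ValueError):
            att.direction_angles(np.zeros(3))


class TestDihedralAngle:
    def test_orthogonal_and_identical(self):
        assert att.dihedral_angle([1, 0, 0], [0, 1, 0]) == pytest.approx(90.0)
        assert att.dihedral_angle([1, 0, 0], [1, 0, 0]) == pytest.approx(0.0)

    def test_symmetric(self):
        rng = np.random.default_rng(7)
        for _ in range(10):
            a, b = rng.normal(size=(2, 3))
            assert att.dihedral_angle(a, b) == pytest.approx(att.dihedral_angle(b, a))

    def test_spherical_triangle_inequality(self):
        rng = np.random.default_rng(8)
        for _ in range(25):
            a, b, c = rng.normal(size=(3, 3))
            ab = att.dihedral_angle(a, b)
            bc = att.dihedral_angle(b, c)
            ac = att.dihedral_angle(a, c)
            assert ac <= ab + bc + 1e-9

    def test_published_left_vertical_canal_angle(self):
        # mean normals of the left anterior and posterior canals make ~101.3 deg
        left_a = np.array([0.1704, -0.5637, 0.8082])
        left_p = np.array([0.1852, -0.6511, -0.7360])
        assert att.dihedral_angle(left_a, left_p) == pytest.approx(101.3, abs=0.1)


class TestDeviationStats:
    def test_all_equal_mean(self):
        v = np.array([0.0, 0.0, 1.0])
        assert att.deviation_stats([v] * 4, v) == (0.0, 0.0)

    def test_two_vectors_ten_degrees_apart(self):
        th = np.radians(10.0)
        a = np.array([np.sin(th / 2), 0, np.cos(th / 2)])
        b = np.array([-np.sin(th / 2), 0, np.cos(th / 2)])
        mean = att.average_unit_normals([a, b])
        m, sd = att.deviation_stats([a, b], mean)
        assert m == pytest.approx(5.0, abs=1e-9)
        assert sd == pytest.approx(0.0, abs=1e-9)

    def test_single_vector(self):
        v = np.array([0.0, 1.0, 0.0])
        assert att.deviation_stats([v], v) == (0.0, 0.0)
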