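"""Rotation-exaggeration shaping transform and template generation."""

import numpy as np
import pytest

import mandrelsim as ms
from mandrelsim.shaping import (
    ShapedPath,
    bend_angles,
    make_template,
    reconstruct_from_template,
    rotation_matrix,
    shape_transform,
)


def _random_path(n_points, seed, step_scale=5.0):
    """Random polyline with gentle joints (no hairpins)."""
    rng = np.random.default_rng(seed)
    d = np.array([1.0, 0.0, 0.0])
    pts = [np.zeros(3)]
    for _ in range(n_points - 1):
        axis = rng.standard_normal(3)
        ang = rng.uniform(0.05, 0.5)
        d = rotation_matrix(axis, ang) @ d
        pts.append(pts[-1] + step_scale * rng.uniform(0.5, 1.5) * d)
    return ms.CatheterPath(np.asarray(pts))


def _two_segment_path(angle_deg):
    a = np.radians(angle_deg)
    return ms.CatheterPath(
        [[0, 0, 0], [10, 0, 0], [10 + 10 * np.cos(a), 10 * np.sin(a), 0]]
    )


class TestRotationMatrix:
    def test_zero_angle_is_identity(self):
        np.testing.assert_allclose(rotation_matrix([1, 2, 3], 0.0), np.eye(3), atol=1e-15)

    def test_quarter_turn_about_z(self):
        R = rotation_matrix([0, 0, 1], np.pi / 2)
        np.testing.assert_allclose(R @ [1, 0, 0], [0, 1, 0], atol=1e-15)

    def test_orthogonality_and_handedness(self):
        rng = np.random.default_rng(42)
        for _ in range(50):
            R = rotation_matrix(rng.standard_normal(3), rng.uniform(-np.pi, np.pi))
            np.testing.assert_allclose(R.T @ R, np.eye(3), atol=1e-12)
            assert np.linalg.det(R) == pytest.approx(1.0, abs=1e-12)

    def test_zero_axis_rejected(self):
        with pytest.raises(ValueError):
            rotation_matrix([0, 0, 0], 1.0)


class TestBendAngles:
    def test_collinear_is_zero(self):
        assert bend_angles([[0, 0, 0], [1, 0, 0], [2, 0, 0]])[0] == pytest.approx(0.0)

    def test_right_angle_elbow(self):
        assert bend_angles([[0, 0, 0], [1, 0, 0], [1, 1, 0]])[0] == pytest.approx(90.0)

    def test_matches_per_joint_brute_force(self):
        path = _random_path(12, seed=5)
        got = bend_angles(path.points, degrees=False)
        for j in range(1, len(path.points) - 1):
            u = path.points[j] - path.points[j - 1]
            v = path.points[j + 1] - path.points[j]
            cosang = (u @ v) / (np.linalg.norm(u) * np.linalg.norm(v))
            expected = np.arccos(np.clip(cosang, -1, 1))
            assert got[j - 1] == pytest.approx(expected, abs=1e-10)

    def test_zero_length_segment_rejected(self):
        with pytest.raises(ValueError):
            bend_angles([[0, 0, 0], [0, 0, 0], [1, 0, 0]])


class TestShapeTransform:
    def test_worked_example_45_to_90(self):
        """A 45-degree bend shaped with factor 2.0 becomes a 90-degree
        mandrel-in bend (the bend relaxes back to 45 on mandrel removal)."""
        path = _two_segment_path(45.0)
        shaped = shape_transform(path, ms.ShapingParams(2.0, path.total_length))
        assert bend_angles(shaped.points)[0] == pytest.approx(90.0, abs=1e-9)

    def test_factor_one_is_identity(self):
        path = _random_path(8, seed=1)
        shaped = shape_transform(path, ms.ShapingParams(1.0, path.total_length))
        np.testing.assert_allclose(shaped.points, path.points, atol=1e-12)

    def test_angle_scaling_and_length_conservation(self):
        path = _random_path(11, seed=7)  # 10 joints... 9 interior joints
        f = 1.5
        shaped = shape_transform(path, ms.ShapingParams(f, path.total_length))
        np.testing.assert_allclose(
            bend_angles(shaped.points, degrees=False),
            f * bend_angles(path.points, degrees=False),
            atol=1e-9,
        )
        np.testing.assert_allclose(
            shaped.segment_lengths,
            np.linalg.norm(np.diff(path.points, axis=0), axis=1),
            atol=1e-9,
        )

    def test_total_length_conserved_for_any_factor(self):
        path = _random_path(15, seed=3)
        for f in (1.0, 1.3, 2.0, 3.0):
            shaped = shape_transform(path, ms.ShapingParams(f, path.total_length))
            assert shaped.segment_lengths.sum() == pytest.approx(
                path.total_length, abs=1e-9
            )

    def test_joints_beyond_shaping_length_unchanged(self):
        path = _random_path(10, seed=2)
        cum = np.concatenate([[0], np.cumsum(np.linalg.norm(np.diff(path.points, axis=0), axis=1))])
        length = cum[4] + 1e-6  # shape only the first 4 joints' span
        shaped = shape_transform(path, ms.ShapingParams(1.5, length))
        orig = bend_angles(path.points, degrees=False)
        new = bend_angles(shaped.points, degrees=False)
        np.testing.assert_allclose(new[:4], 1.5 * orig[:4], atol=1e-9)
        np.testing.assert_allclose(new[4:], orig[4:], atol=1e-9)
        assert shaped.shaped_upto == 4

    def test_tip_segment_is_anchor(self):
        path = _random_path(9, seed=4)
        shaped = shape_transform(path, ms.ShapingParams(2.0, path.total_length))
        np.testing.assert_allclose(shaped.points[:2], path.points[:2], atol=1e-12)

    def test_overbend_clamped_at_180_with_warning(self):
        path = _two_segment_path(100.0)
        with pytest.warns(UserWarning, match="180"):
            shaped = shape_transform(path, ms.ShapingParams(2.0, path.total_length))
        assert bend_angles(shaped.points)[0] == pytest.approx(180.0, abs=1e-6)

    def test_straight_joints_skipped(self):
        path = ms.CatheterPath([[0, 0, 0], [1, 0, 0], [2, 0, 0], [3, 1, 0]])
        shaped = shape_transform(path, ms.ShapingParams(2.0, path.total_length))
        angles = bend_angles(shaped.points, degrees=False)
        assert angles[0] == pytest.approx(0.0, abs=1e-12)

    def test_inverse_per_joint_rotation_recovers_original(self):
        """Shaping with f=2 then rotating each joint back by half its
        (doubled) angle reproduces the input path."""
        path = _random_path(10, seed=11, step_scale=3.0)
        shaped = shape_transform(path, ms.ShapingParams(2.0, path.total_length))
        pts = np.array(shaped.points)
        for j in range(1, len(pts) - 1):
            u = pts[j] - pts[j - 1]
            v = pts[j + 1] - pts[j]
            axis = np.cross(u, v)
            if np.linalg.norm(axis) < 1e-12:
                continue
            un, vn = u / np.linalg.norm(u), v / np.linalg.norm(v)
            theta = np.arccos(np.clip(un @ vn, -1, 1))
            R = rotation_matrix(axis, -theta / 2.0)
            pts[j + 1 :] = (pts[j + 1 :] - pts[j]) @ R.T + pts[j]
        np.testing.assert_allclose(pts, path.points, atol=1e-6)

    def test_invalid_params_rejected(self):
        with pytest.raises(ValueError):
            ms.ShapingParams(0.5, 10.0)
        with pytest.raises(ValueError):
            ms.ShapingParams(2.0, 0.0)


class TestMakeTemplate:
    def test_straight_path_gives_single_zero_bend_row(self):
        shaped = ShapedPath(np.column_stack([np.linspace(0, 10, 30), np.zeros(30), np.zeros(30)]), 0)
        tpl = make_template(shaped, coarsen_tol=0.1)
        assert tpl.rows.shape == (1, 3)
        assert tpl.rows[0, 0] == pytest.approx(10.0)
        assert tpl.rows[0, 1] == 0.0

    def test_planar_path_keeps_single_bending_plane(self):
        """Every joint of a planar path bends in the same plane: each
        torsion row is 0 (same sense) or a half-turn flip (alternating
        sense), never an out-of-plane rotation."""
        pts = np.array(
            [[0, 0, 0], [5, 0, 0], [8, 3, 0], [12, 0, 0], [16, 2, 0]], dtype=float
        )
        tpl = make_template(ShapedPath(pts, 0), coarsen_tol=0.01)
        assert np.abs(np.sin(np.radians(tpl.rows[:, 2]))).max() <= 1e-9
        # same-sense planar bends carry zero torsion
        arc = np.array([[0, 0, 0], [5, 0, 0], [9, 3, 0], [11, 7, 0]], dtype=float)
        tpl2 = make_template(ShapedPath(arc, 0), coarsen_tol=0.01)
        assert np.abs(tpl2.rows[:, 2]).max() <= 1e-9

    def test_reconstruction_matches_shaped_path(self):
        """Round trip: rebuild a polyline from the template and check the
        shaped path lies within coarsen_tol of it (RMS, after alignment)."""
        from scipy.spatial.transform import Rotation

        path = _random_path(20, seed=13, step_scale=2.0)
        shaped = shape_transform(path, ms.ShapingParams(1.4, path.total_length))
        tol = 0.2
        tpl = make_template(shaped, coarsen_tol=tol)
        rebuilt = reconstruct_from_template(tpl)
        # align the rebuilt polyline onto the coarsened shaped path
        from mandrelsim.shaping import _rdp

        simplified = _rdp(shaped.points, tol)
        assert len(rebuilt) == len(simplified)
        rot, _ = Rotation.align_vectors(
            simplified - simplified.mean(axis=0), rebuilt - rebuilt.mean(axis=0)
        )
        aligned = rot.apply(rebuilt - rebuilt.mean(axis=0)) + simplified.mean(axis=0)
        np.testing.assert_allclose(aligned, simplified, atol=1e-6)
        # RMS distance of every shaped point to the rebuilt polyline
        d = [_point_to_polyline(p, aligned) for p in shaped.points]
        assert np.sqrt(np.mean(np.square(d))) <= tol

    def test_too_few_points_rejected(self):
        with pytest.raises(ValueError):
            make_template(ShapedPath(np.zeros((1, 3)), 0))


def _point_to_polyline(p, poly):
    best = np.inf
    for a, b in zip(poly[:-1], poly[1:]):
        ab = b - a
        t = np.clip((p - a) @ ab / (ab @ ab), 0.0, 1.0)
        best = min(best, np.linalg.norm(p - (a + t * ab)))
    return best
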