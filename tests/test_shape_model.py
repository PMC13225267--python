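"""Shape model: reflection, alignment, template, sampling, correspondence."""

import numpy as np
import pytest

from mtasym.shape_model import (align_rigid, build_shape_model,
                                build_template, correspond,
                                farthest_point_sample, flip_sagittal,
                                mean_distance_field, surface_points,
                                template_normals)
from mtasym.types import DistanceField, PipelineError, RigidTransform

from conftest import ellipsoid_field, rotation_z, sphere_field


class TestFlip:
    def test_involution_is_exact(self):
        f = ellipsoid_field((15, 8, 6), shift=(3, 1, -2))
        twice = flip_sagittal(flip_sagittal(f))
        np.testing.assert_array_equal(twice.grid, f.grid)

    def test_symmetric_sphere_unchanged(self):
        f = sphere_field(9.0)
        np.testing.assert_array_equal(flip_sagittal(f).grid, f.grid)

    def test_offcenter_blob_centroid_negates(self):
        f = sphere_field(6.0, n=41, shift=(7.0, 0.0, 0.0))
        c0 = surface_points(f).mean(axis=0) - 20.0
        c1 = surface_points(flip_sagittal(f)).mean(axis=0) - 20.0
        assert c1[0] == pytest.approx(-c0[0], abs=0.1)
        np.testing.assert_allclose(c1[1:], c0[1:], atol=0.1)

    def test_unknown_orientation_rejected(self):
        f = sphere_field(6.0)
        f.orientation = "LPS"
        with pytest.raises(PipelineError, match="orientation"):
            flip_sagittal(f)


class TestAlignment:
    def test_translation_recovered(self):
        f0 = ellipsoid_field((15, 8, 6))
        f1 = ellipsoid_field((15, 8, 6), shift=(5.0, 0.0, 0.0))
        T = align_rigid([f0, f1])
        np.testing.assert_allclose(T[1].t, [-5.0, 0.0, 0.0], atol=0.1)
        np.testing.assert_allclose(T[1].R, np.eye(3), atol=1e-3)

    def test_identical_inputs_give_identity(self):
        f0 = ellipsoid_field((15, 8, 6))
        T = align_rigid([f0, f0.copy()])
        np.testing.assert_allclose(T[1].R, np.eye(3), atol=1e-6)
        np.testing.assert_allclose(T[1].t, 0.0, atol=1e-4)

    def test_rotation_recovered_within_half_degree(self):
        Rz = rotation_z(10.0)
        f0 = ellipsoid_field((15, 8, 6))
        f1 = ellipsoid_field((15, 8, 6), rot=Rz)
        T = align_rigid([f0, f1])
        angle = np.rad2deg(np.arccos(np.clip((np.trace(T[1].R) - 1) / 2,
                                             -1, 1)))
        assert angle == pytest.approx(10.0, abs=0.5)

    def test_single_shape_rejected(self):
        with pytest.raises(PipelineError):
            align_rigid([sphere_field(8.0)])


class TestTemplate:
    def test_identical_spheres_reproduce_radius(self):
        fields = [sphere_field(9.0) for _ in range(3)]
        T = [RigidTransform.identity()] * 3
        verts, _ = build_template(mean_distance_field(fields, T))
        r = np.linalg.norm(verts - 20.0, axis=1)
        assert abs(r.mean() - 9.0) < 1.0

    def test_mean_of_two_spheres_is_middle_sphere(self):
        fields = [sphere_field(9.0), sphere_field(11.0)]
        T = [RigidTransform.identity()] * 2
        verts, _ = build_template(mean_distance_field(fields, T))
        r = np.linalg.norm(verts - 20.0, axis=1)
        assert r.mean() == pytest.approx(10.0, abs=0.2)

    def test_single_phase_mean_rejected(self):
        f = DistanceField(np.full((8, 8, 8), 2.0, np.float32), (1, 1, 1))
        with pytest.raises(PipelineError, match="single-phase"):
            build_template(f)


class TestFarthestPointSampling:
    def test_all_vertices_when_m_equals_n(self):
        rng = np.random.default_rng(0)
        verts = rng.random((30, 3))
        sel = farthest_point_sample(verts, 30)
        assert sorted(sel) == list(range(30))

    def test_two_points_on_a_line_are_endpoints(self):
        verts = np.stack([np.linspace(0, 9, 10),
                          np.zeros(10), np.zeros(10)], axis=1)
        sel = farthest_point_sample(verts, 2)
        assert set(sel) == {0, 9}

    def test_deterministic(self):
        rng = np.random.default_rng(1)
        verts = rng.random((200, 3))
        a = farthest_point_sample(verts, 50)
        b = farthest_point_sample(verts, 50)
        np.testing.assert_array_equal(a, b)

    def test_too_many_points_rejected(self):
        with pytest.raises(PipelineError):
            farthest_point_sample(np.zeros((5, 3)), 6)

    def test_near_uniform_coverage_on_sphere(self):
        from scipy.spatial import cKDTree
        verts, _ = build_template(sphere_field(10.0))
        sel = farthest_point_sample(verts, 128)
        pts = verts[sel]
        d, _ = cKDTree(pts).query(pts, k=2)
        gaps = d[:, 1]
        assert gaps.max() < 3.0 * gaps.mean()


class TestNormals:
    def test_sphere_normals_are_radial(self):
        f = sphere_field(10.0)
        verts, _ = build_template(f)
        pts = verts[farthest_point_sample(verts, 64)]
        nm = template_normals(f, pts)
        np.testing.assert_allclose(np.linalg.norm(nm, axis=1), 1.0, atol=1e-6)
        radial = (pts - 20.0) / np.linalg.norm(pts - 20.0, axis=1,
                                               keepdims=True)
        ang = np.rad2deg(np.arccos(np.clip((nm * radial).sum(1), -1, 1)))
        assert ang.max() < 2.0


class TestCorrespondence:
    def _template(self, radius=10.0):
        f = sphere_field(radius)
        verts, _ = build_template(f)
        pts = verts[farthest_point_sample(verts, 64)]
        return f, pts, template_normals(f, pts)

    def test_identity_subject_recovers_template_points(self):
        f, pts, nm = self._template()
        out, n_fb = correspond(pts, nm, f)
        assert n_fb == 0
        assert np.abs(out - pts).max() < 0.25

    def test_uniform_inflation_displaces_along_normals(self):
        f, pts, nm = self._template(10.0)
        subject = sphere_field(11.0)
        out, n_fb = correspond(pts, nm, subject)
        disp = ((out - pts) * nm).sum(axis=1)
        assert n_fb == 0
        np.testing.assert_allclose(disp, 1.0, atol=0.15)

    def test_missing_crossing_falls_back_to_nearest_surface(self):
        f, pts, nm = self._template(10.0)
        # a far-away small subject: many normal lines never cross its surface
        subject = sphere_field(3.0, shift=(14.0, 0.0, 0.0))
        out, n_fb = correspond(pts, nm, subject, search_radius=5.0)
        assert n_fb > 0
        r = np.linalg.norm(out - np.array([34.0, 20.0, 20.0]), axis=1)
        assert np.abs(r - 3.0).max() < 1.0   # all results lie on the subject


class TestModelInvariants:
    def test_mirror_consistency_and_on_surface(self, mirror_null_cohort):
        from mtasym.grooming import groom
        cov, masks = mirror_null_cohort
        fields = {}
        for pid in cov.index:
            fields[(pid, "left")] = groom(masks[(pid, "left", "hippocampus")])
            fields[(pid, "right_flipped")] = flip_sagittal(
                groom(masks[(pid, "right", "hippocampus")]))
        model = build_shape_model(fields, "hippocampus", 96)
        from mtasym.shape_model import _sample_field
        for pid in cov.index:
            lp = model.subject_points[(pid, "left")]
            rp = model.subject_points[(pid, "right_flipped")]
            # perfectly mirrored structures correspond to identical points
            assert np.abs(lp - rp).max() < 0.25
            T = model.transforms[(pid, "left")]
            vals = _sample_field(fields[(pid, "left")], T.invert(lp))
            assert np.abs(vals).max() < 0.5    # on the zero level set
        np.testing.assert_allclose(
            np.linalg.norm(model.template_normals, axis=1), 1.0, atol=1e-6)
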