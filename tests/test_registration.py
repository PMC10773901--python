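"""Procrustes alignment, LBRP morphing and GPA."""

import numpy as np
import pytest

from craniosynth import registration as reg
from craniosynth.headgen import DeformationParams, HeadMesh, synth_head


def _rot_z(deg):
    a = np.radians(deg)
    return np.array([[np.cos(a), -np.sin(a), 0], [np.sin(a), np.cos(a), 0], [0, 0, 1]])


class TestLandmarkProcrustes:
    def test_identity_on_identical_sets(self):
        lm = synth_head("control", 1).landmarks
        t = reg.landmark_procrustes(lm, lm)
        assert np.allclose(t.rotation, np.eye(3), atol=1e-12)
        assert np.allclose(t.translation, 0, atol=1e-10)
        assert t.scale == pytest.approx(1.0, abs=1e-12)

    def test_recovers_known_similarity_transform(self):
        src = synth_head("control", 1).landmarks
        R, tvec, s = _rot_z(30), np.array([5.0, 0.0, 0.0]), 1.2
        dst = {k: s * R @ v + tvec for k, v in src.items()}
        t = reg.landmark_procrustes(src, dst)
        assert np.allclose(t.rotation, R, atol=1e-8)
        assert np.allclose(t.translation, tvec, atol=1e-8)
        assert t.scale == pytest.approx(1.2, abs=1e-8)
        assert np.linalg.det(t.rotation) == pytest.approx(1.0, abs=1e-10)

    def test_without_scale_fixes_scale_and_leaves_residual(self):
        src = synth_head("control", 1).landmarks
        dst = {k: 1.5 * v for k, v in src.items()}
        t = reg.landmark_procrustes(src, dst, with_scale=False)
        assert t.scale == 1.0
        res = sum(np.sum((t.apply(v[None])[0] - dst[k]) ** 2) for k, v in src.items())
        assert res > 0

    def test_residual_invariant_to_landmark_relabeling(self):
        src = synth_head("control", 2).landmarks
        rng = np.random.default_rng(0)
        dst = {k: v + rng.normal(0, 2, 3) for k, v in src.items()}
        t = reg.landmark_procrustes(src, dst)

        def residual(transform):
            return sum(
                np.sum((transform.apply(v[None])[0] - dst[k]) ** 2) for k, v in src.items()
            )

        # a dict with permuted insertion order must give the same fit
        keys = list(src)[::-1]
        t2 = reg.landmark_procrustes({k: src[k] for k in keys}, {k: dst[k] for k in keys})
        assert residual(t) == pytest.approx(residual(t2), rel=1e-12)

    def test_collinear_landmarks_rejected(self):
        src = {f"p{i}": np.array([float(i), 0.0, 0.0]) for i in range(5)}
        with pytest.raises(ValueError, match="degenerate|collinear"):
            reg.landmark_procrustes(src, src)

    def test_too_few_landmarks_rejected(self):
        src = {"a": np.zeros(3), "b": np.ones(3)}
        with pytest.raises(ValueError, match="at least 3"):
            reg.landmark_procrustes(src, src)


class TestLBRP:
    def test_identical_target_is_fixed_point(self, template):
        out = reg.lbrp_morph(template, template)
        assert np.abs(out - template.vertices).max() < 1e-6

    def test_sphere_onto_ellipsoid_residual(self):
        sphere = synth_head("control", 0, DeformationParams(semiaxes=(85, 85, 85)).zeroed())
        ellipsoid = synth_head("control", 0, DeformationParams().zeroed())
        out, residuals = reg.lbrp_morph(sphere, ellipsoid, return_residuals=True)
        assert residuals[1] < 0.5  # mm, after the low-stiffness stage
        assert residuals[1] <= residuals[0]
        assert out.shape == sphere.vertices.shape  # topology preserved

    def test_infinite_stiffness_limit_keeps_aligned_template(self):
        sphere = synth_head("control", 0, DeformationParams(semiaxes=(85, 85, 85)).zeroed())
        ellipsoid = synth_head("control", 0, DeformationParams().zeroed())
        cfg = reg.MorphConfig(stiffness_high=1e9, stiffness_low=1e8, outer_iterations=3)
        out = reg.lbrp_morph(sphere, ellipsoid, cfg)
        assert np.abs(out - sphere.vertices).max() < 1e-3

    def test_no_correspondences_fails_with_diagnostic(self):
        near = synth_head("control", 0, DeformationParams().zeroed())
        far = HeadMesh(
            near.vertices + 1000.0, near.faces, {k: v + 1000.0 for k, v in near.landmarks.items()},
            "control",
        )
        with pytest.raises(RuntimeError, match="no valid correspondences"):
            reg.lbrp_morph(near, far)

    def test_stiffness_ordering_enforced(self):
        with pytest.raises(ValueError):
            reg.MorphConfig(stiffness_high=1.0, stiffness_low=2.0)


class TestGPA:
    def test_single_shape_returned_unchanged(self):
        h = synth_head("sagittal", 3)
        cs = reg.CorrespondedSet(h.vertices.reshape(1, -1), h.faces, ["sagittal"], ["s0"])
        aligned, mean = reg.gpa(cs)
        assert np.allclose(aligned.shapes[0], cs.shapes[0])
        assert np.allclose(mean, cs.shapes[0])

    def test_rigid_copies_align_to_common_shape(self):
        h = synth_head("metopic", 5)
        rng = np.random.default_rng(1)
        shapes = []
        for _ in range(6):
            q, _ = np.linalg.qr(rng.normal(size=(3, 3)))
            if np.linalg.det(q) < 0:
                q[:, 0] *= -1
            shapes.append((h.vertices @ q.T + rng.normal(size=3) * 30).reshape(-1))
        cs = reg.CorrespondedSet(np.array(shapes), h.faces, ["metopic"] * 6, [f"s{i}" for i in range(6)])
        aligned, mean = reg.gpa(cs)
        pts = aligned.as_points()
        assert np.abs(pts - pts.mean(axis=0)).max() < 1e-6
        assert np.abs(pts[0].reshape(-1) - mean).max() < 1e-6

    def test_prealigned_set_converges_immediately(self):
        h = synth_head("control", 2)
        cs = reg.CorrespondedSet(
            np.tile(h.vertices.reshape(-1), (4, 1)), h.faces, ["control"] * 4, list("abcd")
        )
        aligned, mean = reg.gpa(cs, max_iterations=1)
        assert np.allclose(aligned.shapes, cs.shapes, atol=1e-9)

    def test_invariance_to_rigid_motion_of_inputs(self):
        rng = np.random.default_rng(2)
        heads = [synth_head("control", 40 + i) for i in range(5)]
        cs = reg.CorrespondedSet(
            np.stack([h.vertices.reshape(-1) for h in heads]),
            heads[0].faces,
            ["control"] * 5,
            [h.subject_id or str(i) for i, h in enumerate(heads)],
        )
        _, mean_a = reg.gpa(cs)
        q, _ = np.linalg.qr(rng.normal(size=(3, 3)))
        if np.linalg.det(q) < 0:
            q[:, 0] *= -1
        moved = np.stack(
            [(s.reshape(-1, 3) @ q.T + rng.normal(size=3) * 10).reshape(-1) for s in cs.shapes]
        )
        cs2 = reg.CorrespondedSet(moved, cs.template_faces, cs.labels, cs.subject_ids)
        _, mean_b = reg.gpa(cs2)
        # means agree up to one rigid alignment
        a, b = mean_a.reshape(-1, 3), mean_b.reshape(-1, 3)
        aligned_b = reg._rigid_align(b, a)
        assert np.abs(aligned_b - a).max() < 1e-4


def test_register_cohort_gives_dense_correspondence(corresponded, fixture_cohort):
    assert corresponded.shapes.shape == (len(fixture_cohort), 642 * 3)
    assert corresponded.labels == [h.label for h in fixture_cohort]
    # morphed templates sit close to their targets
    tm = fixture_cohort[0].to_trimesh()
    d = reg.point_to_surface_distance(corresponded.as_points()[0], tm)
    assert d.mean() < 0.3  # mm


def test_corresponded_set_roundtrip(tmp_path, corresponded):
    path = tmp_path / "cs.npz"
    corresponded.save(path, metadata={"note": "test"})
    back = reg.CorrespondedSet.load(path)
    assert np.allclose(back.shapes, corresponded.shapes)
    assert back.labels == corresponded.labels
    assert back.subject_ids == corresponded.subject_ids
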