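"""Area weights, weighted PCA and shape sampling."""

import numpy as np
import pytest
import trimesh

from craniosynth import registration as reg
from craniosynth import ssm
from craniosynth.headgen import synth_head
from craniosynth.registration import CorrespondedSet


class TestVertexAreaWeights:
    def test_icosahedron_symmetry(self):
        ico = trimesh.creation.icosahedron()
        w = ssm.vertex_area_weights(ico)
        assert len(w) == 12
        assert np.allclose(w, w[0])
        assert w.sum() == pytest.approx(ico.area, rel=1e-12)

    def test_weights_conserve_total_area(self, small_heads):
        for h in small_heads["sagittal"][:3]:
            tm = h.to_trimesh()
            w = ssm.vertex_area_weights(h)
            assert w.sum() == pytest.approx(tm.area, rel=1e-9)

    def test_refining_a_region_lowers_per_vertex_weight_but_conserves_region(self):
        """Subdividing the cap region redistributes weight over more vertices
        while the regional weight total is conserved; this is what makes the
        weighted PCA insensitive to sampling density."""
        sphere = trimesh.creation.icosphere(subdivisions=2, radius=80.0)
        cap = lambda m: np.asarray(m.vertices)[:, 2] > 0.55 * 80.0
        w0 = ssm.vertex_area_weights(sphere)
        region0 = w0[cap(sphere)]
        cap_faces = np.flatnonzero(cap(sphere)[sphere.faces].all(axis=1))
        refined = sphere.subdivide(cap_faces)
        w1 = ssm.vertex_area_weights(refined)
        region1 = w1[cap(refined)]
        # per-vertex weights in the refined region decrease ...
        assert np.median(region1) < 0.5 * np.median(region0)
        # ... but the regional weight mass is conserved to < 1%
        assert region1.sum() == pytest.approx(region0.sum(), rel=0.01)

    def test_zero_area_mesh_rejected(self):
        degenerate = trimesh.Trimesh(
            np.zeros((3, 3)), np.array([[0, 1, 2]]), process=False
        )
        with pytest.raises(ValueError, match="zero surface area"):
            ssm.vertex_area_weights(degenerate)


def _one_class_set(shapes, faces, label="control"):
    return CorrespondedSet(np.asarray(shapes), faces, [label] * len(shapes), [f"s{i}" for i in range(len(shapes))])


class TestBuildShapeModel:
    def test_identical_shapes_give_zero_components(self):
        h = synth_head("control", 1)
        cs = _one_class_set([h.vertices.reshape(-1)] * 3, h.faces)
        model = ssm.build_shape_model(cs)
        assert model.n_components == 0
        assert model.eigenvalues.size == 0

    def test_single_mode_family_recovers_direction(self):
        h = synth_head("control", 1)
        base = h.vertices.reshape(-1)
        rng = np.random.default_rng(0)
        u = rng.normal(size=base.size)
        u /= np.linalg.norm(u)
        shapes = [base + a * u for a in (-1.0, 0.0, 1.0)]
        cs = _one_class_set(shapes, h.faces)
        w = np.ones(len(h.vertices))
        model = ssm.build_shape_model(cs, weights=w)
        assert model.n_components == 1
        v = model.components[:, 0]
        cos = abs(v @ u) / np.linalg.norm(v)
        assert cos > 1 - 1e-8
        # eigenvalue equals the sample variance along u: var([-1,0,1]) = 1
        assert model.eigenvalues[0] == pytest.approx(1.0, rel=1e-8)

    def test_weighted_orthonormality_and_descending_eigenvalues(self, corresponded):
        control = corresponded.subset([i for i, l in enumerate(corresponded.labels) if l == "control"])
        aligned, _ = reg.gpa(control)
        model = ssm.build_shape_model(aligned)
        w3 = np.repeat(model.vertex_weights, 3)
        gram = model.components.T @ (w3[:, None] * model.components)
        assert np.allclose(gram, np.eye(model.n_components), atol=1e-8)
        assert np.all(np.diff(model.eigenvalues) <= 1e-12)

    def test_variance_threshold_semantics(self, corresponded):
        """Retained components reach >= 95% of total variance and one fewer
        component stays below 95%."""
        control = corresponded.subset([i for i, l in enumerate(corresponded.labels) if l == "control"])
        aligned, _ = reg.gpa(control)
        model = ssm.build_shape_model(aligned, variance_fraction=0.95)
        full = ssm.build_shape_model(aligned, variance_fraction=1.0)
        total = full.eigenvalues.sum()
        q = model.n_components
        assert full.eigenvalues[:q].sum() / total >= 0.95
        assert full.eigenvalues[: q - 1].sum() / total < 0.95

    def test_eigenvalues_match_dense_covariance_oracle(self):
        """Brute-force eigen-decomposition of the weighted covariance."""
        rng = np.random.default_rng(1)
        K, m = 12, 30
        X = rng.normal(size=(K, 3 * m))
        w = rng.uniform(0.5, 2.0, size=m)
        w3 = np.repeat(w, 3)
        h = synth_head("control", 0)
        cs = _one_class_set(X, h.faces[: m - 2])
        model_full = ssm.build_shape_model(cs, weights=w, variance_fraction=1.0)
        Xc = X - X.mean(axis=0)
        C = np.sqrt(w3)[:, None] * (Xc.T @ Xc / (K - 1)) * np.sqrt(w3)[None, :]
        eig = np.linalg.eigvalsh(C)[::-1][: model_full.n_components]
        assert np.allclose(model_full.eigenvalues, eig, rtol=1e-8)

    def test_mixed_classes_and_tiny_sets_rejected(self):
        h = synth_head("control", 1)
        mixed = CorrespondedSet(
            np.tile(h.vertices.reshape(-1), (2, 1)), h.faces, ["control", "sagittal"], ["a", "b"]
        )
        with pytest.raises(ValueError, match="one class"):
            ssm.build_shape_model(mixed)
        single = _one_class_set([h.vertices.reshape(-1)], h.faces)
        with pytest.raises(ValueError, match="at least 2"):
            ssm.build_shape_model(single)


@pytest.fixture(scope="module")
def model(corresponded):
    control = corresponded.subset(
        [i for i, l in enumerate(corresponded.labels) if l == "control"]
    )
    aligned, _ = reg.gpa(control)
    return ssm.build_shape_model(aligned)


class TestSampleShapes:
    def test_zero_coefficients_return_mean(self, model):
        out = ssm.sample_shapes(model, alphas=np.zeros((1, model.n_components)))
        assert np.allclose(out[0], model.mean_shape)

    def test_unit_coefficient_has_sqrt_eigenvalue_weighted_norm(self, model):
        j = 0
        e = np.zeros((1, model.n_components))
        e[0, j] = 1.0
        out = ssm.sample_shapes(model, alphas=e)
        norm = ssm.weighted_norm(out[0] - model.mean_shape, model.vertex_weights)
        assert norm == pytest.approx(np.sqrt(model.eigenvalues[j]), rel=1e-8)

    def test_sample_variance_matches_eigenvalues(self, model):
        samples = ssm.sample_shapes(model, n=5000, seed=11)
        coeffs = np.stack([ssm.project(model, s) for s in samples])
        # coefficients are standard normal: variance 1 per retained direction
        var = coeffs.var(axis=0, ddof=1)
        assert np.all(np.abs(var - 1.0) < 0.05)

    def test_determinism_and_alpha_validation(self, model):
        a = ssm.sample_shapes(model, n=3, seed=5)
        b = ssm.sample_shapes(model, n=3, seed=5)
        assert np.array_equal(a, b)
        with pytest.raises(ValueError, match="length"):
            ssm.sample_shapes(model, alphas=np.zeros((1, model.n_components + 1)))

    def test_training_set_reconstruction_within_truncation_error(self, corresponded):
        control = corresponded.subset(
            [i for i, l in enumerate(corresponded.labels) if l == "control"]
        )
        aligned, _ = reg.gpa(control)
        model = ssm.build_shape_model(aligned, variance_fraction=0.95)
        X = aligned.shapes
        w3 = np.repeat(model.vertex_weights, 3)
        err = 0.0
        tot = 0.0
        for x in X:
            alpha = ssm.project(model, x)
            rec = ssm.sample_shapes(model, alphas=alpha[None])[0]
            err += np.sum(w3 * (x - rec) ** 2)
            tot += np.sum(w3 * (x - X.mean(axis=0)) ** 2)
        assert err / tot <= (1 - 0.95) + 1e-6

    def test_model_roundtrip(self, tmp_path, model):
        path = tmp_path / "model.npz"
        model.save(path)
        back = ssm.ShapeModel.load(path)
        assert np.allclose(back.mean_shape, model.mean_shape)
        assert np.allclose(back.eigenvalues, model.eigenvalues)
        assert back.class_label == model.class_label
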