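"""Dense correspondence across head meshes.

Pipeline: (1) landmark-based Procrustes alignment of a template to each
target (rotation, translation, isotropic scale, closed form); (2) two-stage
non-rigid template morphing with a Laplace-Beltrami (cotangent) regularizer
— a high-stiffness stage that captures the global shape and a low-stiffness
stage that lets the template settle onto the target; (3) generalized
Procrustes analysis (rotation + translation only, size deliberately kept so
that scale variation enters the shape statistics).

The morphed templates share the template topology and point IDs, which is
the prerequisite for shape PCA.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import scipy.sparse as sp
import scipy.sparse.linalg as spla
from scipy.spatial import cKDTree
import trimesh

from .headgen import CohortSpec, DeformationParams, HeadMesh, synth_cohort


@dataclass
class SimilarityTransform:
    rotation: np.ndarray  # 3x3, det +1
    translation: np.ndarray  # (3,)
    scale: float

    def apply(self, points: np.ndarray) -> np.ndarray:
        return self.scale * points @ self.rotation.T + self.translation


@dataclass
class MorphConfig:
    stiffness_high: float = 100.0
    stiffness_low: float = 1.0
    outer_iterations: int = 10
    correspondence_max_distance: float = 10.0  # mm
    correspondence_max_normal_angle: float = 60.0  # degrees

    def __post_init__(self):
        if not (self.stiffness_high > self.stiffness_low > 0):
            raise ValueError("require stiffness_high > stiffness_low > 0")


@dataclass
class CorrespondedSet:
    """K shapes sharing template topology, each flattened to a 3m-vector."""

    shapes: np.ndarray  # (K, 3m)
    template_faces: np.ndarray
    labels: list[str]
    subject_ids: list[str] = field(default_factory=list)

    @property
    def n_vertices(self) -> int:
        return self.shapes.shape[1] // 3

    def as_points(self) -> np.ndarray:
        return self.shapes.reshape(len(self.labels), -1, 3)

    def subset(self, mask) -> "CorrespondedSet":
        mask = np.asarray(mask)
        idx = np.flatnonzero(mask) if mask.dtype == bool else mask
        return CorrespondedSet(
            self.shapes[idx],
            self.template_faces,
            [self.labels[i] for i in idx],
            [self.subject_ids[i] for i in idx] if self.subject_ids else [],
        )

    def save(self, path: str | Path, metadata: dict | None = None) -> None:
        np.savez_compressed(
            path,
            shapes=self.shapes,
            faces=self.template_faces,
            labels=np.asarray(self.labels),
            subject_ids=np.asarray(self.subject_ids),
            metadata=np.asarray(json.dumps(metadata or {})),
        )

    @classmethod
    def load(cls, path: str | Path) -> "CorrespondedSet":
        with np.load(path, allow_pickle=False) as z:
            return cls(
                z["shapes"],
                z["faces"],
                [str(x) for x in z["labels"]],
                [str(x) for x in z["subject_ids"]],
            )


# -- landmark Procrustes ------------------------------------------------------


def landmark_procrustes(
    source_landmarks: dict[str, np.ndarray],
    target_landmarks: dict[str, np.ndarray],
    with_scale: bool = True,
) -> SimilarityTransform:
    """Least-squares similarity transform mapping source landmarks onto target.

    Closed form via SVD of the cross-covariance (Umeyama). Rejects
    configurations with fewer than 3 landmarks or (near-)collinear layouts.
    """
    names = sorted(set(source_landmarks) & set(target_landmarks))
    if len(names) != len(source_landmarks) or len(names) != len(target_landmarks):
        raise ValueError("source and target landmark names must match")
    if len(names) < 3:
        raise ValueError("need at least 3 landmarks")
    src = np.array([source_landmarks[n] for n in names], dtype=float)
    dst = np.array([target_landmarks[n] for n in names], dtype=float)

    mu_s, mu_d = src.mean(0), dst.mean(0)
    sc, dc = src - mu_s, dst - mu_d
    cov = dc.T @ sc / len(names)
    u, s, vt = np.linalg.svd(cov)
    if s[1] < 1e-9 * max(s[0], 1e-30):
        raise ValueError("degenerate (collinear) landmark configuration")
    d = np.sign(np.linalg.det(u @ vt))
    diag = np.diag([1.0, 1.0, d])
    rotation = u @ diag @ vt
    if with_scale:
        var_s = (sc**2).sum() / len(names)
        scale = float(np.trace(np.diag(s) @ diag) / var_s)
    else:
        scale = 1.0
    translation = mu_d - scale * rotation @ mu_s
    return SimilarityTransform(rotation, translation, scale)


# -- Laplace-Beltrami regularized morphing ------------------------------------


def cotangent_laplacian(vertices: np.ndarray, faces: np.ndarray) -> sp.csr_matrix:
    """Unnormalized cotangent Laplacian (rows sum to zero).

    Degenerate triangles fall back to uniform (unit) edge weights.
    """
    m = len(vertices)
    ii, jj, ww = [], [], []
    for a, b, c in ((0, 1, 2), (1, 2, 0), (2, 0, 1)):
        va, vb, vc = (vertices[faces[:, k]] for k in (a, b, c))
        e1, e2 = va - vc, vb - vc
        cross = np.linalg.norm(np.cross(e1, e2), axis=1)
        dot = (e1 * e2).sum(1)
        with np.errstate(divide="ignore", invalid="ignore"):
            cot = dot / cross
        cot = np.where(np.isfinite(cot), cot, 1.0)
        cot = np.clip(cot, -1e4, 1e4)
        w = 0.5 * cot
        ii.extend([faces[:, a], faces[:, b]])
        jj.extend([faces[:, b], faces[:, a]])
        ww.extend([w, w])
    W = sp.coo_matrix(
        (np.concatenate(ww), (np.concatenate(ii), np.concatenate(jj))), shape=(m, m)
    ).tocsr()
    return sp.diags(np.asarray(W.sum(axis=1)).ravel()) - W


def _vertex_normals(vertices: np.ndarray, faces: np.ndarray) -> np.ndarray:
    """Area-weighted vertex normals (vectorized)."""
    fn = np.cross(
        vertices[faces[:, 1]] - vertices[faces[:, 0]],
        vertices[faces[:, 2]] - vertices[faces[:, 0]],
    )
    vn = np.zeros_like(vertices)
    for k in range(3):
        np.add.at(vn, faces[:, k], fn)
    norm = np.linalg.norm(vn, axis=1, keepdims=True)
    norm[norm == 0] = 1.0
    return vn / norm


def point_to_surface_distance(points: np.ndarray, mesh: trimesh.Trimesh, k: int = 6) -> np.ndarray:
    """Exact distance from each point to the surface, restricted to the
    triangles incident to each point's k nearest mesh vertices."""
    points = np.atleast_2d(points)
    tree = cKDTree(mesh.vertices)
    _, nearest = tree.query(points, k=k)
    vertex_faces = np.asarray(mesh.vertex_faces)  # (m, maxdeg), padded with -1
    cand = vertex_faces[nearest].reshape(len(points), -1)  # (n, k*maxdeg)
    pidx, cidx = np.nonzero(cand >= 0)
    fids = cand[pidx, cidx]
    tris = np.asarray(mesh.triangles)
    closest = trimesh.triangles.closest_point(tris[fids], points[pidx])
    d = np.linalg.norm(closest - points[pidx], axis=1)
    dists = np.full(len(points), np.inf)
    np.minimum.at(dists, pidx, d)
    return dists


def lbrp_morph(
    template: HeadMesh,
    target: HeadMesh,
    config: MorphConfig | None = None,
    return_residuals: bool = False,
):
    """Morph the (landmark-aligned) template onto the target.

    Each outer iteration finds nearest-neighbour correspondences on the
    target (rejecting pairs beyond the distance / normal-angle gates) and
    solves ``min_d sum_sel ||v0 + d - c||^2 + beta ||L d||^2`` for the
    displacement field d, where L is the template's cotangent Laplacian.
    Stage 1 uses ``stiffness_high``, stage 2 ``stiffness_low``.

    Returns the morphed vertex array (template topology preserved); with
    ``return_residuals=True`` also the mean point-to-surface residual after
    each stage.
    """
    cfg = config or MorphConfig()
    v0 = template.vertices.astype(float)
    faces = template.faces
    L = cotangent_laplacian(v0, faces)
    LtL = (L.T @ L).tocsr()
    target_tm = target.to_trimesh()
    t_verts = np.asarray(target_tm.vertices)
    t_normals = np.asarray(target_tm.vertex_normals)
    tree = cKDTree(t_verts)
    cos_gate = np.cos(np.radians(cfg.correspondence_max_normal_angle))

    current = v0.copy()
    residuals = []
    for beta in (cfg.stiffness_high, cfg.stiffness_low):
        for _ in range(cfg.outer_iterations):
            dist, nn = tree.query(current)
            normals = _vertex_normals(current, faces)
            ok = (dist <= cfg.correspondence_max_distance) & (
                (normals * t_normals[nn]).sum(1) >= cos_gate
            )
            if not ok.any():
                raise RuntimeError(
                    "lbrp_morph: no valid correspondences "
                    f"(beta={beta}, max distance {cfg.correspondence_max_distance} mm)"
                )
            sel = sp.diags(ok.astype(float))
            A = (sel + beta * LtL).tocsc()
            rhs = ok[:, None] * (t_verts[nn] - v0)
            try:
                solve = spla.factorized(A)
            except RuntimeError as err:  # pragma: no cover - singular system
                raise RuntimeError(f"lbrp_morph: singular system (beta={beta})") from err
            d = np.column_stack([solve(rhs[:, k]) for k in range(3)])
            current = v0 + d
        residuals.append(float(point_to_surface_distance(current, target_tm).mean()))
    if return_residuals:
        return current, residuals
    return current


# -- generalized Procrustes analysis ------------------------------------------


def _rigid_align(points: np.ndarray, ref: np.ndarray) -> np.ndarray:
    """Rotation+translation (no scale) aligning ``points`` onto ``ref``."""
    mu_p, mu_r = points.mean(0), ref.mean(0)
    cov = (ref - mu_r).T @ (points - mu_p)
    u, _, vt = np.linalg.svd(cov)
    d = np.sign(np.linalg.det(u @ vt))
    rot = u @ np.diag([1.0, 1.0, d]) @ vt
    return (points - mu_p) @ rot.T + mu_r


def gpa(
    shapes: CorrespondedSet, tolerance: float = 1e-7, max_iterations: int = 50
) -> tuple[CorrespondedSet, np.ndarray]:
    """Generalized Procrustes analysis: iteratively align every shape to the
    running mean by rotation and translation only (scale kept)."""
    pts = shapes.as_points().copy()
    if len(pts) == 0:
        raise ValueError("gpa needs at least one shape")
    mean = pts[0].copy()
    for _ in range(max_iterations):
        pts = np.stack([_rigid_align(p, mean) for p in pts])
        new_mean = pts.mean(0)
        change = float(np.abs(new_mean - mean).max())
        mean = new_mean
        if change < tolerance:
            break
    aligned = CorrespondedSet(
        pts.reshape(len(pts), -1), shapes.template_faces, list(shapes.labels), list(shapes.subject_ids)
    )
    return aligned, mean.reshape(-1)


# -- cohort-level drivers ------------------------------------------------------


def build_template(n: int = 20, seed: int = 12345, subdivisions: int = 3) -> HeadMesh:
    """Mean of a small, separately generated control cohort, used as the
    morphing template (stands in for an externally published mean shape)."""
    params = DeformationParams(plagiocephaly_prob=0.0)
    spec = CohortSpec(counts={"control": n}, seed=seed, params=params, subdivisions=subdivisions)
    cohort = synth_cohort(spec)
    verts = np.mean([h.vertices for h in cohort], axis=0)
    landmarks = {
        k: np.mean([h.landmarks[k] for h in cohort], axis=0) for k in cohort[0].landmarks
    }
    return HeadMesh(verts, cohort[0].faces.copy(), landmarks, "control", "template")


def landmark_vertex_ids(mesh: HeadMesh) -> dict[str, int]:
    """Nearest template vertex for each landmark (for landmark transfer to
    morphed or sampled shapes)."""
    tree = cKDTree(mesh.vertices)
    return {name: int(tree.query(pt)[1]) for name, pt in mesh.landmarks.items()}


def register_cohort(
    cohort: list[HeadMesh],
    template: HeadMesh | None = None,
    config: MorphConfig | None = None,
) -> CorrespondedSet:
    """Landmark-align the template to every target and morph it on.

    Returns the morphed templates as a corresponded set (in each target's
    coordinate frame; run :func:`gpa` before statistics).
    """
    template = template or build_template(subdivisions=_subdiv_of(cohort[0]))
    shapes, labels, ids = [], [], []
    for target in cohort:
        t = landmark_procrustes(template.landmarks, target.landmarks, with_scale=True)
        aligned = HeadMesh(
            t.apply(template.vertices),
            template.faces,
            {k: t.apply(v[None])[0] for k, v in template.landmarks.items()},
            target.label,
        )
        morphed = lbrp_morph(aligned, target, config)
        shapes.append(morphed.reshape(-1))
        labels.append(target.label)
        ids.append(target.subject_id)
    return CorrespondedSet(np.asarray(shapes), template.faces.copy(), labels, ids)


def _subdiv_of(mesh: HeadMesh) -> int:
    # icosphere vertex counts: 12, 42, 162, 642, 2562, ...
    counts = {12: 0, 42: 1, 162: 2, 642: 3, 2562: 4}
    return counts.get(len(mesh.vertices), 3)
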