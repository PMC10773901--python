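"""Per-class statistical shape models.

Each class gets its own point-distribution model built independently from
the corresponded, GPA-aligned shapes of that class: area-weighted PCA of the
3m-dimensional vertex coordinate vectors, truncated at 95% of the normalized
variance. New shapes are synthesized as

    s = s_mean + V Lambda^(1/2) alpha,      alpha ~ N(0, I_q)

where V holds the weighted principal components and Lambda the eigenvalue
diagonal of the weighted sample covariance.

The per-vertex weights counterbalance non-uniform point density: each vertex
is weighted by one third of the summed areas of its incident triangles
(barycentric area lumping), so densely sampled regions do not dominate the
covariance.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import trimesh

from ._pca import pca_sample, weighted_pca
from .headgen import HeadMesh
from .registration import CorrespondedSet


@dataclass
class ShapeModel:
    mean_shape: np.ndarray  # (3m,) mm
    components: np.ndarray  # (3m, q), weighted-orthonormal
    eigenvalues: np.ndarray  # (q,), mm^2, descending
    vertex_weights: np.ndarray  # (m,), mm^2
    class_label: str
    variance_fraction_retained: float
    template_faces: np.ndarray | None = None

    @property
    def n_components(self) -> int:
        return self.components.shape[1]

    def save(self, path: str | Path) -> None:
        np.savez_compressed(
            path,
            mean_shape=self.mean_shape,
            components=self.components,
            eigenvalues=self.eigenvalues,
            vertex_weights=self.vertex_weights,
            faces=self.template_faces if self.template_faces is not None else np.empty((0, 3), int),
            metadata=np.asarray(
                json.dumps(
                    {
                        "class_label": self.class_label,
                        "variance_fraction_retained": self.variance_fraction_retained,
                    }
                )
            ),
        )

    @classmethod
    def load(cls, path: str | Path) -> "ShapeModel":
        with np.load(path, allow_pickle=False) as z:
            meta = json.loads(str(z["metadata"]))
            faces = z["faces"]
            return cls(
                z["mean_shape"],
                z["components"],
                z["eigenvalues"],
                z["vertex_weights"],
                meta["class_label"],
                meta["variance_fraction_retained"],
                faces if faces.size else None,
            )


def vertex_area_weights(mesh: HeadMesh | trimesh.Trimesh) -> np.ndarray:
    """Barycentric area lumping: weight_i = sum(area of incident faces) / 3.

    The weights sum to the total surface area.
    """
    tm = mesh.to_trimesh() if isinstance(mesh, HeadMesh) else mesh
    areas = np.asarray(tm.area_faces)
    if areas.sum() <= 0:
        raise ValueError("mesh has zero surface area")
    w = np.zeros(len(tm.vertices))
    faces = np.asarray(tm.faces)
    for k in range(3):
        np.add.at(w, faces[:, k], areas / 3.0)
    return w


def build_shape_model(
    shapes: CorrespondedSet,
    weights: np.ndarray | None = None,
    variance_fraction: float = 0.95,
) -> ShapeModel:
    """Weighted PCA of one class's aligned shapes.

    ``weights`` is a length-m per-vertex vector; by default it is computed
    from the mean shape's geometry on the template topology. Shapes of mixed
    classes are rejected: each class's model must be independent.
    """
    labels = set(shapes.labels)
    if len(labels) != 1:
        raise ValueError(f"shapes must all belong to one class, got {sorted(labels)}")
    if shapes.shapes.shape[0] < 2:
        raise ValueError("need at least 2 shapes")
    label = labels.pop()
    m = shapes.n_vertices
    mean_pts = shapes.shapes.mean(axis=0).reshape(m, 3)
    if weights is None:
        weights = vertex_area_weights(trimesh.Trimesh(mean_pts, shapes.template_faces, process=False))
    weights = np.asarray(weights, dtype=float)
    if weights.shape != (m,):
        raise ValueError("weights must have one entry per vertex")
    w3 = np.repeat(weights, 3)
    mean, components, eigenvalues = weighted_pca(shapes.shapes, w3, variance_fraction)
    return ShapeModel(
        mean, components, eigenvalues, weights, label, variance_fraction, shapes.template_faces
    )


def sample_shapes(
    model: ShapeModel,
    n: int = 1000,
    seed: int = 0,
    alphas: np.ndarray | None = None,
    clamp_sigma: float | None = None,
) -> np.ndarray:
    """Draw n shapes (n x 3m) with standard-normal coefficients.

    ``alphas`` overrides the random draw (must be (n, q)); ``clamp_sigma``
    optionally truncates coefficients to +-clamp_sigma (off by default: the
    coefficient distribution is a plain Gaussian).
    """
    q = model.n_components
    if alphas is None:
        rng = np.random.default_rng(seed)
        alphas = rng.standard_normal((n, q))
        if clamp_sigma is not None:
            alphas = np.clip(alphas, -clamp_sigma, clamp_sigma)
    else:
        alphas = np.atleast_2d(np.asarray(alphas, dtype=float))
        if alphas.shape[1] != q:
            raise ValueError(f"alpha vectors must have length {q}")
    return pca_sample(model.mean_shape, model.components, model.eigenvalues, alphas)


def weighted_norm(x: np.ndarray, vertex_weights: np.ndarray) -> float:
    """Norm induced by the per-vertex weights on a 3m-vector."""
    w3 = np.repeat(vertex_weights, 3)
    return float(np.sqrt(np.sum(w3 * np.asarray(x) ** 2)))


def project(model: ShapeModel, shape: np.ndarray) -> np.ndarray:
    """Coefficients alpha of a shape under the model (weighted projection)."""
    w3 = np.repeat(model.vertex_weights, 3)
    centered = np.asarray(shape) - model.mean_shape
    raw = model.components.T @ (w3 * centered)
    with np.errstate(divide="ignore"):
        return raw / np.sqrt(model.eigenvalues)
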