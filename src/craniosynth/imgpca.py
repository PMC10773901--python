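"""Per-class PCA directly on vectorized distance maps.

Ordinary PCA (uniform pixel weights; same core as the 3-D shape model) is
fitted separately for each class, truncated at 95% normalized variance, and
sampled with standard-normal coefficients:

    i = i_mean + V Lambda^(1/2) alpha .

Synthesized images are clipped back into [0, 1]; the fraction of clipped
pixels is recorded on the model (``last_clip_rate``).
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from ._pca import pca_sample, weighted_pca
from .distmap import DistanceMap


@dataclass
class ImagePCAModel:
    mean_image: np.ndarray  # (H*W,)
    components: np.ndarray  # (H*W, q), orthonormal
    eigenvalues: np.ndarray  # (q,), descending
    class_label: str
    variance_fraction_retained: float
    image_shape: tuple[int, int] = (28, 28)
    last_clip_rate: float = 0.0

    @property
    def n_components(self) -> int:
        return self.components.shape[1]

    def save(self, path: str | Path) -> None:
        np.savez_compressed(
            path,
            mean_image=self.mean_image,
            components=self.components,
            eigenvalues=self.eigenvalues,
            metadata=np.asarray(
                json.dumps(
                    {
                        "class_label": self.class_label,
                        "variance_fraction_retained": self.variance_fraction_retained,
                        "image_shape": list(self.image_shape),
                    }
                )
            ),
        )

    @classmethod
    def load(cls, path: str | Path) -> "ImagePCAModel":
        with np.load(path, allow_pickle=False) as z:
            meta = json.loads(str(z["metadata"]))
            return cls(
                z["mean_image"],
                z["components"],
                z["eigenvalues"],
                meta["class_label"],
                meta["variance_fraction_retained"],
                tuple(meta["image_shape"]),
            )


def build_image_pca(
    images: list[DistanceMap], variance_fraction: float = 0.95
) -> ImagePCAModel:
    """Fit one class's image PCA. Mixed classes are rejected."""
    if len(images) < 2:
        raise ValueError("need at least 2 images")
    labels = {im.label for im in images}
    if len(labels) != 1:
        raise ValueError(f"images must all belong to one class, got {sorted(labels)}")
    shapes = {im.pixels.shape for im in images}
    if len(shapes) != 1:
        raise ValueError("images must share one size")
    shape = shapes.pop()
    X = np.stack([im.pixels.reshape(-1) for im in images])
    mean, components, eigenvalues = weighted_pca(X, np.ones(X.shape[1]), variance_fraction)
    return ImagePCAModel(mean, components, eigenvalues, labels.pop(), variance_fraction, shape)


def sample_images(
    model: ImagePCAModel,
    n: int = 1000,
    seed: int = 0,
    alphas: np.ndarray | None = None,
    clip: bool = True,
) -> list[DistanceMap]:
    """Draw n images with standard-normal coefficients, reshaped to 2-D and
    clipped to the valid intensity range."""
    q = model.n_components
    if alphas is None:
        alphas = np.random.default_rng(seed).standard_normal((n, q))
    else:
        alphas = np.atleast_2d(np.asarray(alphas, dtype=float))
        if alphas.shape[1] != q:
            raise ValueError(f"alpha vectors must have length {q}")
    flat = pca_sample(model.mean_image, model.components, model.eigenvalues, alphas)
    if clip:
        model.last_clip_rate = float(np.mean((flat < 0) | (flat > 1)))
        flat = np.clip(flat, 0.0, 1.0)
    return [
        DistanceMap(row.reshape(model.image_shape), model.class_label, {"source": "pca"})
        for row in flat
    ]


def project(model: ImagePCAModel, image: DistanceMap) -> np.ndarray:
    """Coefficients of an image under the model."""
    centered = image.pixels.reshape(-1) - model.mean_image
    with np.errstate(divide="ignore"):
        return (model.components.T @ centered) / np.sqrt(model.eigenvalues)
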