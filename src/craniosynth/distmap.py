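"""2-D "distance map" encoding of a 3-D head surface.

A landmark-derived head coordinate frame (origin at the tragion midpoint,
axes anterior/left/superior) defines a spherical ray grid: rows sample
elevation from the vertex (top row) down to the tragion plane, columns
sample a full 360-degree azimuth sweep with the anterior midline at the
center column (the azimuth axis is circular). Each pixel is the distance
from the origin to the first surface intersection along its ray, divided by
a fixed d_max (absolute normalization), clipped to [0, 1].

Absolute normalization means adding a constant intensity to a map
corresponds to radially re-scaling the head, and a horizontal flip about the
center column corresponds to anatomical left/right mirroring — the two
properties the classifier's augmentations rely on.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import imageio.v3 as iio
import numpy as np
import pandas as pd

from .headgen import HeadMesh

DEFAULT_SIZE = 28
DEFAULT_D_MAX = 200.0  # mm
DEFAULT_ELEVATION_RANGE = (0.0, 90.0)  # tragion plane .. vertex, degrees


@dataclass
class HeadFrame:
    origin: np.ndarray  # (3,) mm
    axes: np.ndarray  # rows: anterior, left, superior; orthonormal, right-handed

    @property
    def anterior(self):
        return self.axes[0]

    @property
    def left(self):
        return self.axes[1]

    @property
    def superior(self):
        return self.axes[2]


@dataclass
class DistanceMap:
    pixels: np.ndarray  # (H, W) in [0, 1]
    label: str
    meta: dict = field(default_factory=dict)

    @property
    def size(self) -> int:
        return self.pixels.shape[0]


def head_frame(landmarks: dict[str, np.ndarray]) -> HeadFrame:
    """Anatomical frame from the tragion pair and the nasion."""
    for name in ("tragion_left", "tragion_right", "nasion"):
        if name not in landmarks:
            raise ValueError(f"missing landmark {name!r}")
    tl = np.asarray(landmarks["tragion_left"], dtype=float)
    tr = np.asarray(landmarks["tragion_right"], dtype=float)
    nas = np.asarray(landmarks["nasion"], dtype=float)
    origin = 0.5 * (tl + tr)
    left = tl - tr
    nl = np.linalg.norm(left)
    if nl < 1e-9:
        raise ValueError("coincident tragions")
    left = left / nl
    ant = nas - origin
    ant = ant - (ant @ left) * left
    na = np.linalg.norm(ant)
    if na < 1e-9:
        raise ValueError("nasion lies on the tragion axis")
    ant = ant / na
    superior = np.cross(ant, left)
    return HeadFrame(origin, np.vstack([ant, left, superior]))


def ray_grid(frame: HeadFrame, size: int, elevation_range=DEFAULT_ELEVATION_RANGE) -> np.ndarray:
    """Unit ray directions, shape (size*size, 3); row-major pixel order.

    Elevation spans ``elevation_range`` top-row-high at pixel centers;
    azimuth spans 360 degrees with 180 (anterior midline) at the center
    column and wraps circularly.
    """
    lo, hi = elevation_range
    rows = np.arange(size) + 0.5
    cols = np.arange(size) + 0.5
    elev = np.radians(hi - rows * (hi - lo) / size)
    azim = np.radians(cols * 360.0 / size)
    el, az = np.meshgrid(elev, azim, indexing="ij")
    # azimuth measured from the anterior direction: 180 deg maps to anterior
    horiz = np.cos(az - np.pi)[..., None] * frame.anterior + np.sin(az - np.pi)[..., None] * frame.left
    dirs = np.cos(el)[..., None] * horiz + np.sin(el)[..., None] * frame.superior
    return dirs.reshape(-1, 3)


def _moller_trumbore(origin, dirs, v0, e1, e2, face_idx=None):
    """Nearest positive intersection distance per ray over the given
    triangles; ``face_idx`` (P, k) optionally restricts each ray to its own
    candidate set. Returns inf where a ray misses."""
    tvec = origin[None, :] - v0  # (T,3), same for every ray (single origin)
    qvec = np.cross(tvec, e1)  # (T,3)
    tq = np.einsum("tk,tk->t", qvec, e2)  # (T,)
    if face_idx is None:
        E2, E1, TV, QV, TQ = e2[None], e1[None], tvec[None], qvec[None], tq[None]
    else:
        E2, E1, TV, QV, TQ = e2[face_idx], e1[face_idx], tvec[face_idx], qvec[face_idx], tq[face_idx]
    d = dirs[:, None, :]  # (P,1,3)
    pvec = np.cross(d, E2)
    det = np.einsum("ptk,ptk->pt", pvec, np.broadcast_to(E1, pvec.shape))
    with np.errstate(divide="ignore", invalid="ignore"):
        inv = 1.0 / det
        u = np.einsum("ptk,ptk->pt", pvec, np.broadcast_to(TV, pvec.shape)) * inv
        v = np.einsum("ptk,ptk->pt", np.broadcast_to(QV, pvec.shape), np.broadcast_to(d, pvec.shape)) * inv
        t = TQ * inv
    eps = 1e-9
    valid = (np.abs(det) > 1e-12) & (u >= -eps) & (v >= -eps) & (u + v <= 1 + eps) & (t > eps)
    return np.where(valid, t, np.inf).min(axis=1)


def _ray_cast(origin, dirs, vertices, faces, k_candidates=48):
    """Ray casting accelerated by a KD-tree over triangle centroid
    directions; rays that miss all candidates fall back to a full scan."""
    from scipy.spatial import cKDTree

    v0 = vertices[faces[:, 0]]
    e1 = vertices[faces[:, 1]] - v0
    e2 = vertices[faces[:, 2]] - v0
    centroids = (vertices[faces[:, 0]] + vertices[faces[:, 1]] + vertices[faces[:, 2]]) / 3.0
    cdir = centroids - origin
    norms = np.linalg.norm(cdir, axis=1, keepdims=True)
    norms[norms == 0] = 1.0
    k = min(k_candidates, len(faces))
    _, cand = cKDTree(cdir / norms).query(dirs, k=k)
    out = _moller_trumbore(origin, dirs, v0, e1, e2, np.atleast_2d(cand))
    missed = ~np.isfinite(out)
    if missed.any():
        out[missed] = _moller_trumbore(origin, dirs[missed], v0, e1, e2)
    return out


def encode_distance_map(
    mesh: HeadMesh | None = None,
    frame: HeadFrame | None = None,
    *,
    vertices: np.ndarray | None = None,
    faces: np.ndarray | None = None,
    label: str | None = None,
    size: int = DEFAULT_SIZE,
    d_max: float = DEFAULT_D_MAX,
    elevation_range=DEFAULT_ELEVATION_RANGE,
    subject_id: str = "",
) -> DistanceMap:
    """Encode a head surface into a size x size distance map.

    Accepts either a :class:`HeadMesh` (frame derived from its landmarks
    unless given) or raw ``vertices``/``faces`` plus an explicit ``frame``.
    """
    if mesh is not None:
        vertices = mesh.vertices
        faces = mesh.faces
        label = label if label is not None else mesh.label
        subject_id = subject_id or mesh.subject_id
        if frame is None:
            frame = head_frame(mesh.landmarks)
    if vertices is None or faces is None or frame is None:
        raise ValueError("need a HeadMesh or vertices+faces+frame")
    dirs = ray_grid(frame, size, elevation_range)
    dists = _ray_cast(frame.origin, dirs, np.asarray(vertices, float), np.asarray(faces))
    if not np.all(np.isfinite(dists)):
        miss = np.argwhere(~np.isfinite(dists).reshape(size, size))
        raise RuntimeError(f"ray missed the surface at pixels {miss[:5].tolist()} (non-watertight input?)")
    pixels = np.clip(dists.reshape(size, size) / d_max, 0.0, 1.0)
    meta = {
        "azimuth_origin": "anterior at center column",
        "elevation_range": list(elevation_range),
        "d_max_mm": d_max,
        "subject_id": subject_id,
    }
    return DistanceMap(pixels, label or "", meta)


# -- I/O ------------------------------------------------------------------------


def save_png(dm: DistanceMap, path: str | Path) -> None:
    iio.imwrite(Path(path), np.round(dm.pixels * 255).astype(np.uint8))


def load_png(path: str | Path, label: str = "", meta: dict | None = None) -> DistanceMap:
    pixels = np.asarray(iio.imread(Path(path)), dtype=float) / 255.0
    return DistanceMap(pixels, label, meta or {})


def save_dataset(maps: list[DistanceMap], path: str | Path, source: str = "clinical") -> Path:
    """Array archive + manifest CSV (image index, label, source)."""
    path = Path(path)
    np.savez_compressed(
        path.with_suffix(".npz"),
        images=np.stack([m.pixels for m in maps]),
        labels=np.asarray([m.label for m in maps]),
    )
    manifest = pd.DataFrame(
        {
            "image_index": np.arange(len(maps)),
            "label": [m.label for m in maps],
            "source": source,
            "subject_id": [m.meta.get("subject_id", "") for m in maps],
        }
    )
    manifest.to_csv(path.with_suffix(".csv"), index=False)
    return path.with_suffix(".npz")


def load_dataset(path: str | Path) -> list[DistanceMap]:
    path = Path(path)
    with np.load(path.with_suffix(".npz"), allow_pickle=False) as z:
        images, labels = z["images"], z["labels"]
    manifest = path.with_suffix(".csv")
    subject_ids = [""] * len(images)
    if manifest.exists():
        df = pd.read_csv(manifest, keep_default_na=False)
        subject_ids = list(df["subject_id"].astype(str))
    return [
        DistanceMap(img, str(lab), {"subject_id": sid})
        for img, lab, sid in zip(images, labels, subject_ids)
    ]
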