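"""Synthetic 3D head cohort generator.

Generates watertight icosphere-topology head meshes with 10 cephalometric
landmarks and one of four diagnosis labels: ``control``, ``coronal``
(coronal suture fusion: anterior plagiocephaly / brachycephaly), ``metopic``
(trigonocephaly) and ``sagittal`` (scaphocephaly). The cohort emulates a
clinical photogrammetric dataset with class ratios 56/5/14/25% (278, 25, 69
and 124 subjects; 496 in total).

Each head is a baseline ellipsoid radial field (anteroposterior ~95 mm,
lateral ~75 mm, vertical ~80 mm semi-axes, with per-subject jitter)
modulated by multiplicative raised-cosine bumps in azimuth/elevation that
mimic the deformity of each class:

* sagittal  — anteroposterior elongation plus lateral narrowing (low
  cephalic index),
* metopic   — a narrow frontal keel with para-median frontal flattening
  (pointed forehead),
* coronal   — anterior flattening, unilateral (random side) or bilateral
  with compensatory widening,
* control   — no deformity, or mild posterior-oblique flattening
  (positional plagiocephaly) with configurable probability.

Coordinate convention: +x anterior, +y left, +z superior (mm). Azimuth is
measured from the anterior axis toward the left; elevation from the
axial (tragion) plane toward the vertex.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
import trimesh

CLASSES = ("control", "coronal", "metopic", "sagittal")

#: default class counts matching the emulated clinical cohort
DEFAULT_COUNTS = {"control": 278, "coronal": 25, "metopic": 69, "sagittal": 124}

#: landmark name -> (azimuth deg, elevation deg) on the parametric sphere
LANDMARK_ANGLES = {
    "nasion": (0.0, 10.0),
    "glabella": (0.0, 25.0),
    "subnasale": (0.0, -15.0),
    "gnathion": (0.0, -40.0),
    "tragion_left": (90.0, 0.0),
    "tragion_right": (-90.0, 0.0),
    "exocanthion_left": (25.0, 5.0),
    "exocanthion_right": (-25.0, 5.0),
    "euryon_left": (90.0, 25.0),
    "euryon_right": (-90.0, 25.0),
}

BILATERAL_PAIRS = (
    ("tragion_left", "tragion_right"),
    ("exocanthion_left", "exocanthion_right"),
    ("euryon_left", "euryon_right"),
)


@dataclass
class HeadMesh:
    """Watertight triangular head surface with landmarks and a label."""

    vertices: np.ndarray  # (m, 3) mm
    faces: np.ndarray  # (f, 3) int
    landmarks: dict[str, np.ndarray]  # 10 named 3-D points, mm
    label: str
    subject_id: str = ""

    def to_trimesh(self) -> trimesh.Trimesh:
        return trimesh.Trimesh(self.vertices, self.faces, process=False)

    @property
    def landmark_names(self) -> list[str]:
        return sorted(self.landmarks)


@dataclass
class DeformationParams:
    """Per-class deformation amplitude ranges (uniform draws)."""

    semiaxes: tuple[float, float, float] = (95.0, 75.0, 80.0)
    axis_jitter: float = 0.04  # relative, per semi-axis
    scale_jitter: float = 0.05  # relative, global
    sagittal_elongation: tuple[float, float] = (0.10, 0.18)
    sagittal_narrowing: tuple[float, float] = (0.08, 0.14)
    metopic_keel: tuple[float, float] = (0.05, 0.09)
    metopic_flattening: tuple[float, float] = (0.07, 0.13)
    coronal_flattening: tuple[float, float] = (0.10, 0.16)
    coronal_widening: tuple[float, float] = (0.05, 0.10)
    coronal_bilateral_prob: float = 0.2
    plagiocephaly_prob: float = 0.3
    plagiocephaly_amplitude: tuple[float, float] = (0.03, 0.07)

    def zeroed(self) -> "DeformationParams":
        """All jitters and amplitudes set to zero (exact base ellipsoid)."""
        z = (0.0, 0.0)
        return replace(
            self,
            axis_jitter=0.0,
            scale_jitter=0.0,
            sagittal_elongation=z,
            sagittal_narrowing=z,
            metopic_keel=z,
            metopic_flattening=z,
            coronal_flattening=z,
            coronal_widening=z,
            plagiocephaly_prob=0.0,
            plagiocephaly_amplitude=z,
        )


@dataclass
class CohortSpec:
    counts: dict[str, int] = field(default_factory=lambda: dict(DEFAULT_COUNTS))
    seed: int = 0
    params: DeformationParams = field(default_factory=DeformationParams)
    subdivisions: int = 3


_SPHERE_CACHE: dict[int, trimesh.Trimesh] = {}


def unit_sphere(subdivisions: int = 3) -> trimesh.Trimesh:
    """Icosphere rotated so one vertex sits exactly on the anterior pole +x."""
    if subdivisions not in _SPHERE_CACHE:
        ico = trimesh.creation.icosphere(subdivisions=subdivisions, radius=1.0)
        v = np.asarray(ico.vertices)
        pole = v[np.argmax(v[:, 0])]
        target = np.array([1.0, 0.0, 0.0])
        axis = np.cross(pole, target)
        s = np.linalg.norm(axis)
        c = float(pole @ target)
        if s < 1e-12:
            rot = np.eye(3)
        else:
            k = axis / s
            kx = np.array([[0, -k[2], k[1]], [k[2], 0, -k[0]], [-k[1], k[0], 0]])
            rot = np.eye(3) + np.sin(np.arctan2(s, c)) * kx + (1 - c) * kx @ kx
        v = v @ rot.T
        v /= np.linalg.norm(v, axis=1, keepdims=True)
        _SPHERE_CACHE[subdivisions] = trimesh.Trimesh(v, ico.faces, process=False)
    return _SPHERE_CACHE[subdivisions]


def _angles(dirs: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """(azimuth, elevation) in degrees for unit directions."""
    az = np.degrees(np.arctan2(dirs[..., 1], dirs[..., 0]))
    el = np.degrees(np.arcsin(np.clip(dirs[..., 2], -1.0, 1.0)))
    return az, el


def _angdiff(a: np.ndarray, center: float) -> np.ndarray:
    return (a - center + 180.0) % 360.0 - 180.0


def _raised_cos(d: np.ndarray, width: float) -> np.ndarray:
    x = np.clip(np.abs(d) / width, 0.0, 1.0)
    return 0.5 * (1.0 + np.cos(np.pi * x))


def _bump(az, el, c_az, w_az, c_el, w_el, amp) -> np.ndarray:
    return amp * _raised_cos(_angdiff(az, c_az), w_az) * _raised_cos(el - c_el, w_el)


def _class_bumps(label: str, rng: np.random.Generator, p: DeformationParams) -> list[tuple]:
    """(c_az, w_az, c_el, w_el, amplitude) tuples for one subject."""
    u = rng.uniform
    if label == "sagittal":
        a = u(*p.sagittal_elongation)
        b = u(*p.sagittal_narrowing)
        return [
            (0.0, 60.0, 20.0, 70.0, a),
            (180.0, 60.0, 20.0, 70.0, a),
            (90.0, 50.0, 25.0, 60.0, -b),
            (-90.0, 50.0, 25.0, 60.0, -b),
        ]
    if label == "metopic":
        k = u(*p.metopic_keel)
        f = u(*p.metopic_flattening)
        return [
            (0.0, 22.0, 25.0, 60.0, k),
            (45.0, 32.0, 25.0, 60.0, -f),
            (-45.0, 32.0, 25.0, 60.0, -f),
        ]
    if label == "coronal":
        a = u(*p.coronal_flattening)
        w = u(*p.coronal_widening)
        bilateral = rng.random() < p.coronal_bilateral_prob
        if bilateral:
            return [
                (40.0, 50.0, 30.0, 60.0, -a),
                (-40.0, 50.0, 30.0, 60.0, -a),
                (90.0, 45.0, 20.0, 60.0, w),
                (-90.0, 45.0, 20.0, 60.0, w),
            ]
        side = 1.0 if rng.random() < 0.5 else -1.0
        return [(side * 40.0, 50.0, 30.0, 60.0, -a)]
    if label == "control":
        if rng.random() < p.plagiocephaly_prob:
            amp = u(*p.plagiocephaly_amplitude)
            side = 1.0 if rng.random() < 0.5 else -1.0
            return [(side * 135.0, 50.0, 25.0, 60.0, -amp)]
        return []
    raise ValueError(f"unknown class label: {label!r}")


def _radial_field(dirs, semiaxes, bumps):
    a, b, c = semiaxes
    r = 1.0 / np.sqrt(
        (dirs[..., 0] / a) ** 2 + (dirs[..., 1] / b) ** 2 + (dirs[..., 2] / c) ** 2
    )
    az, el = _angles(dirs)
    factor = np.ones_like(r)
    for c_az, w_az, c_el, w_el, amp in bumps:
        factor += _bump(az, el, c_az, w_az, c_el, w_el, amp)
    return r * factor


def synth_head(
    label: str,
    seed: int,
    params: DeformationParams | None = None,
    subdivisions: int = 3,
    subject_id: str = "",
) -> HeadMesh:
    """Generate one labeled synthetic head mesh.

    Deterministic under (label, seed, params). Raises ``ValueError`` for an
    unknown label or if the deformation drives any radius non-positive.
    """
    if label not in CLASSES:
        raise ValueError(f"unknown class label: {label!r}")
    if subdivisions < 2:
        raise ValueError("subdivision level must be >= 2")
    p = params or DeformationParams()
    rng = np.random.default_rng(seed)

    jit = rng.uniform(1 - p.axis_jitter, 1 + p.axis_jitter, size=3) if p.axis_jitter > 0 else np.ones(3)
    scale = rng.uniform(1 - p.scale_jitter, 1 + p.scale_jitter) if p.scale_jitter > 0 else 1.0
    semiaxes = scale * jit * np.asarray(p.semiaxes)
    bumps = _class_bumps(label, rng, p)

    sphere = unit_sphere(subdivisions)
    dirs = np.asarray(sphere.vertices)
    radii = _radial_field(dirs, semiaxes, bumps)
    if np.any(radii <= 0):
        bad = int(np.argmin(radii))
        raise ValueError(
            f"deformation produced non-positive radius {radii[bad]:.3f} mm at vertex {bad}"
        )
    vertices = dirs * radii[:, None]

    landmarks = {}
    for name, (az, el) in LANDMARK_ANGLES.items():
        azr, elr = np.radians(az), np.radians(el)
        d = np.array([np.cos(elr) * np.cos(azr), np.cos(elr) * np.sin(azr), np.sin(elr)])
        landmarks[name] = d * float(_radial_field(d[None], semiaxes, bumps)[0])

    return HeadMesh(vertices, np.asarray(sphere.faces).copy(), landmarks, label, subject_id)


def synth_cohort(spec: CohortSpec) -> list[HeadMesh]:
    """Generate the full labeled cohort described by ``spec``.

    Per-subject seeds are derived from (cohort seed, global index), so any
    subject is reproducible in isolation.
    """
    for label, n in spec.counts.items():
        if label not in CLASSES:
            raise ValueError(f"unknown class label: {label!r}")
        if n < 0:
            raise ValueError("counts must be nonnegative")
    cohort = []
    idx = 0
    for label in CLASSES:
        for _ in range(spec.counts.get(label, 0)):
            sub_seed = int(np.random.SeedSequence((spec.seed, idx)).generate_state(1)[0])
            cohort.append(
                synth_head(
                    label,
                    sub_seed,
                    spec.params,
                    spec.subdivisions,
                    subject_id=f"s{idx:04d}_{label}",
                )
            )
            idx += 1
    return cohort


def mirror(mesh: HeadMesh) -> HeadMesh:
    """Anatomical left/right mirror: negate the lateral axis, swap bilateral
    landmarks, and rewind faces to keep outward orientation."""
    v = mesh.vertices.copy()
    v[:, 1] *= -1
    faces = mesh.faces[:, ::-1].copy()
    lm = {}
    swap = {a: b for a, b in BILATERAL_PAIRS} | {b: a for a, b in BILATERAL_PAIRS}
    for name, pt in mesh.landmarks.items():
        q = pt.copy()
        q[1] *= -1
        lm[swap.get(name, name)] = q
    return HeadMesh(v, faces, lm, mesh.label, mesh.subject_id + "_mirror")


# -- scalar shape indices -----------------------------------------------------


def shape_indices(mesh: HeadMesh) -> dict[str, float]:
    """Three scalar indices separating the four classes.

    cephalic_index: 100 x maximal width / maximal length.
    frontal_angle_index: median radius at the frontal midline divided by the
        mean para-median (+-45 deg) radius in the 15-40 deg elevation band; a
        metopic keel raises it.
    anterior_asymmetry: relative left/right difference of anterior-oblique
        radii; high for unilateral coronal synostosis.
    """
    v = mesh.vertices
    length = v[:, 0].max() - v[:, 0].min()
    width = v[:, 1].max() - v[:, 1].min()
    r = np.linalg.norm(v, axis=1)
    az, el = _angles(v / r[:, None])
    band = (el > 15) & (el < 40)

    def mean_r(center, half_width=15.0):
        m = band & (np.abs(_angdiff(az, center)) < half_width)
        return float(r[m].mean())

    frontal = mean_r(0.0)
    para = 0.5 * (mean_r(45.0) + mean_r(-45.0))
    left_ant, right_ant = mean_r(40.0), mean_r(-40.0)
    return {
        "cephalic_index": 100.0 * width / length,
        "frontal_angle_index": frontal / para,
        "anterior_asymmetry": abs(left_ant - right_ant) / (0.5 * (left_ant + right_ant)),
    }


def cephalic_index(mesh: HeadMesh) -> float:
    return shape_indices(mesh)["cephalic_index"]


# -- I/O ----------------------------------------------------------------------


def save_cohort(cohort: list[HeadMesh], out_dir: str | Path, fmt: str = "ply") -> Path:
    """Write meshes (PLY or OBJ), landmark sidecar JSONs and a manifest CSV."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rows = []
    for mesh in cohort:
        mesh_path = out_dir / f"{mesh.subject_id}.{fmt}"
        lm_path = out_dir / f"{mesh.subject_id}.landmarks.json"
        mesh.to_trimesh().export(mesh_path)
        lm_path.write_text(
            json.dumps({k: [float(x) for x in v] for k, v in mesh.landmarks.items()}, indent=0)
        )
        rows.append(
            {
                "subject_id": mesh.subject_id,
                "label": mesh.label,
                "mesh_path": mesh_path.name,
                "landmarks_path": lm_path.name,
            }
        )
    manifest = out_dir / "manifest.csv"
    pd.DataFrame(rows).to_csv(manifest, index=False)
    return manifest


def load_cohort(manifest_path: str | Path) -> list[HeadMesh]:
    manifest_path = Path(manifest_path)
    base = manifest_path.parent
    df = pd.read_csv(manifest_path)
    cohort = []
    for row in df.itertuples():
        tm = trimesh.load(base / row.mesh_path, process=False)
        lm = {
            k: np.asarray(v, dtype=float)
            for k, v in json.loads((base / row.landmarks_path).read_text()).items()
        }
        cohort.append(
            HeadMesh(np.asarray(tm.vertices), np.asarray(tm.faces), lm, row.label, row.subject_id)
        )
    return cohort
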