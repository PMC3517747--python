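"""Label-volume and surface-mesh I/O.

The measurement pipeline starts from segmented anatomy: either an integer
label volume (NIfTI, voxel spacing in mm) or triangulated surface meshes
(PLY/STL, vertex units mm).  This module provides the two containers
(:class:`LabelVolume`, :class:`SurfaceMesh`), tri-linear upsampling of label
fields, and isosurface reconstruction of a label's boundary.

Conventions
-----------
* World coordinates are mm.  Voxel indices are 0-based and use the
  voxel-center convention: voxel ``(i, j, k)`` has its center at
  ``origin + spacing * (i, j, k)``.
* Label interpolation is done per label on 0/1 indicator fields, never on
  the raw integer codes, so interpolation cannot invent intermediate labels.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import nibabel as nib
import numpy as np
import trimesh
from scipy import ndimage
from skimage import measure as skmeasure

#: Anatomical label codes used throughout the package.
LABELS = {
    "background": 0,
    "femur": 1,
    "tibia": 2,
    "patella": 3,
    "tibial_plateau": 4,
    "trochlea": 5,
    "femoral_shaft": 6,
    "condyle_medial": 7,
    "condyle_lateral": 8,
}

LABEL_NAMES = {v: k for k, v in LABELS.items()}


class GeometryError(ValueError):
    """Raised for contract violations on volumes and meshes."""


# ---------------------------------------------------------------------------
# LabelVolume
# ---------------------------------------------------------------------------


@dataclass
class LabelVolume:
    """Voxel grid of integer anatomical labels with mm spacing.

    Parameters
    ----------
    labels
        3D integer array; 0 is background.
    spacing
        Voxel spacing per axis in mm, strictly positive.
    origin
        World position (mm) of the center of voxel (0, 0, 0).
    axis_orientation
        Free-form descriptor of the anatomical axis convention
        (default ``"RAS"``-style: +x lateral, +y anterior, +z proximal
        for a right knee).
    """

    labels: np.ndarray
    spacing: tuple[float, float, float]
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)
    axis_orientation: str = "RAS"

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels)
        if self.labels.ndim != 3:
            raise GeometryError("label array must be 3D")
        if not np.issubdtype(self.labels.dtype, np.integer):
            if not np.allclose(self.labels, np.rint(self.labels)):
                raise GeometryError("non-integer labels in volume")
            self.labels = np.rint(self.labels).astype(np.int16)
        self.spacing = tuple(float(s) for s in self.spacing)
        self.origin = tuple(float(o) for o in self.origin)
        if len(self.spacing) != 3 or any(s <= 0 for s in self.spacing):
            raise GeometryError(f"spacing must be strictly positive, got {self.spacing}")
        present = set(np.unique(self.labels).tolist())
        unknown = present - set(LABELS.values())
        if unknown:
            raise GeometryError(f"unknown label codes in volume: {sorted(unknown)}")

    @property
    def present_labels(self) -> list[int]:
        return sorted(int(v) for v in np.unique(self.labels) if v != 0)

    def affine(self) -> np.ndarray:
        aff = np.eye(4)
        aff[:3, :3] = np.diag(self.spacing)
        aff[:3, 3] = self.origin
        return aff


def read_label_volume(path: str | Path) -> LabelVolume:
    """Read a NIfTI label volume, preserving spacing and origin.

    Raises
    ------
    GeometryError
        If the file is missing, carries no spacing metadata, or stores
        non-integer voxel values.
    """
    path = Path(path)
    if not path.exists():
        raise GeometryError(f"no such volume file: {path}")
    img = nib.load(str(path))
    zooms = img.header.get_zooms()[:3]
    if any(not np.isfinite(z) or z <= 0 for z in zooms):
        raise GeometryError(f"missing or invalid spacing metadata in {path}")
    data = np.asanyarray(img.dataobj)
    if not np.allclose(data, np.rint(data)):
        raise GeometryError(f"non-integer labels in {path}")
    origin = tuple(float(v) for v in img.affine[:3, 3])
    return LabelVolume(np.rint(data).astype(np.int16), tuple(map(float, zooms)), origin)


def write_label_volume(volume: LabelVolume, path: str | Path) -> None:
    img = nib.Nifti1Image(volume.labels.astype(np.int16), volume.affine())
    img.header.set_zooms(volume.spacing)
    nib.save(img, str(path))


def trilinear_upsample(
    volume: LabelVolume, factor: int | tuple[int, int, int]
) -> LabelVolume:
    """Tri-linearly interpolate each label's indicator field and re-label.

    The output grid keeps the voxel-center convention: along an axis with
    ``n`` voxels and integer factor ``f`` the output has ``f*(n-1)+1``
    voxels at spacing ``spacing/f``, with endpoint voxel centers coinciding
    with the input's.  Each output voxel takes the label whose interpolated
    indicator is largest, provided it reaches 0.5; otherwise background.
    """
    if np.isscalar(factor):
        factor = (int(factor),) * 3
    factor = tuple(int(f) for f in factor)
    if any(f < 1 for f in factor):
        raise GeometryError(f"upsample factor must be >= 1 per axis, got {factor}")
    if factor == (1, 1, 1):
        return LabelVolume(
            volume.labels.copy(), volume.spacing, volume.origin, volume.axis_orientation
        )
    shape = volume.labels.shape
    out_shape = tuple(f * (n - 1) + 1 for n, f in zip(shape, factor))
    grids = np.meshgrid(
        *[np.arange(m) / f for m, f in zip(out_shape, factor)], indexing="ij"
    )
    coords = np.stack(grids)
    best_score = np.full(out_shape, -1.0, dtype=np.float32)
    best_label = np.zeros(out_shape, dtype=np.int16)
    for lab in volume.present_labels:
        indicator = (volume.labels == lab).astype(np.float32)
        interp = ndimage.map_coordinates(indicator, coords, order=1, mode="nearest")
        take = interp > best_score
        best_score[take] = interp[take]
        best_label[take] = lab
    best_label[best_score < 0.5] = 0
    spacing = tuple(s / f for s, f in zip(volume.spacing, factor))
    return LabelVolume(best_label, spacing, volume.origin, volume.axis_orientation)


# ---------------------------------------------------------------------------
# SurfaceMesh
# ---------------------------------------------------------------------------


@dataclass
class SurfaceMesh:
    """Triangulated surface in mm world coordinates."""

    vertices: np.ndarray
    faces: np.ndarray
    tag: str | None = None

    def __post_init__(self) -> None:
        self.vertices = np.asarray(self.vertices, dtype=np.float64)
        self.faces = np.asarray(self.faces, dtype=np.int64)
        if self.vertices.ndim != 2 or self.vertices.shape[1] != 3:
            raise GeometryError("vertices must be (n, 3)")
        if self.faces.ndim != 2 or self.faces.shape[1] != 3:
            raise GeometryError("faces must be (m, 3)")
        if self.faces.size and (
            self.faces.min() < 0 or self.faces.max() >= len(self.vertices)
        ):
            raise GeometryError("face indices out of range")

    # -- derived quantities -------------------------------------------------

    def triangle_areas(self) -> np.ndarray:
        v = self.vertices
        f = self.faces
        cross = np.cross(v[f[:, 1]] - v[f[:, 0]], v[f[:, 2]] - v[f[:, 0]])
        return 0.5 * np.linalg.norm(cross, axis=1)

    def triangle_centroids(self) -> np.ndarray:
        return self.vertices[self.faces].mean(axis=1)

    @property
    def area(self) -> float:
        return float(self.triangle_areas().sum())

    def as_trimesh(self) -> trimesh.Trimesh:
        return trimesh.Trimesh(self.vertices, self.faces, process=False)

    def cleaned(self, min_area: float = 1e-12) -> "SurfaceMesh":
        """Drop zero-area triangles and unreferenced vertices."""
        keep = self.triangle_areas() > min_area
        faces = self.faces[keep]
        used = np.unique(faces)
        remap = np.full(len(self.vertices), -1, dtype=np.int64)
        remap[used] = np.arange(len(used))
        return SurfaceMesh(self.vertices[used], remap[faces], self.tag)

    def transformed(self, rotation: np.ndarray | None = None,
                    translation: np.ndarray | None = None) -> "SurfaceMesh":
        v = self.vertices
        if rotation is not None:
            v = v @ np.asarray(rotation).T
        if translation is not None:
            v = v + np.asarray(translation)
        return SurfaceMesh(v, self.faces.copy(), self.tag)

    # -- I/O ----------------------------------------------------------------

    def save(self, path: str | Path) -> None:
        """Write PLY (ASCII by default) or STL, chosen by extension."""
        path = Path(path)
        mesh = self.as_trimesh()
        if path.suffix.lower() == ".ply":
            path.write_bytes(mesh.export(file_type="ply", encoding="ascii"))
        else:
            mesh.export(str(path))

    @classmethod
    def load(cls, path: str | Path, tag: str | None = None) -> "SurfaceMesh":
        path = Path(path)
        if not path.exists():
            raise GeometryError(f"no such mesh file: {path}")
        mesh = trimesh.load(str(path), force="mesh", process=False)
        return cls(np.asarray(mesh.vertices), np.asarray(mesh.faces), tag)


def extract_surface(
    volume: LabelVolume, label: int, smooth_vox: float = 1.0
) -> SurfaceMesh:
    """Isosurface of one label's indicator field at level 0.5 (marching cubes).

    The 0/1 indicator is smoothed with a Gaussian of ``smooth_vox`` voxels
    before contouring: the raw binary field yields a staircase isosurface
    whose area overestimates by ~9% for curved structures, while the
    smoothed field's 0.5-level surface tracks the underlying anatomy
    (``smooth_vox=0`` disables smoothing).  Vertices are returned in mm
    world coordinates; degenerate faces are removed.  Raises
    :class:`GeometryError` if the label is absent.
    """
    mask = volume.labels == label
    if not mask.any():
        raise GeometryError(
            f"label {label} ({LABEL_NAMES.get(label, '?')}) not present in volume"
        )
    pad = max(2, int(np.ceil(3 * smooth_vox)))
    indicator = np.pad(mask.astype(np.float32), pad)
    if smooth_vox > 0:
        indicator = ndimage.gaussian_filter(indicator, smooth_vox)
    if indicator.max() <= 0.5:  # structure thinner than the smoothing kernel
        indicator = np.pad(mask.astype(np.float32), pad)
    verts, faces, _, _ = skmeasure.marching_cubes(
        indicator, level=0.5, spacing=volume.spacing
    )
    verts = verts + np.asarray(volume.origin) - pad * np.asarray(volume.spacing)
    mesh = SurfaceMesh(verts, faces, tag=LABEL_NAMES.get(label))
    return mesh.cleaned()
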