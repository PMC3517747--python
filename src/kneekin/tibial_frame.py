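"""Tibia-based anatomical coordinate system.

The tibial plateau's articular surface defines the reference frame for all
tibiofemoral measurements: the origin is the area-centroid of the plateau
surface and the axes come from a principal-axes construction —

* ``z_t`` : plateau mean surface normal (smallest-variance principal
  direction), sign chosen proximal;
* ``x_t`` : in-plane direction of largest spread (medio-lateral), sign
  chosen lateral;
* ``y_t = z_t x x_t`` : completes the right-handed frame, pointing anterior.

Sign disambiguation uses an :class:`OrientationHints` record holding rough
world-space direction guesses, trivially available from scan orientation.
For near-circular plateaus, where the two in-plane principal directions are
not distinguishable, ``x_t`` falls back to the lateral hint projected into
the plateau plane so that frames never flip between acquisitions of one
subject.

Sign conventions adopted package-wide: lateral +x, anterior +y, proximal +z
(for a right knee); all anterior/posterior signs in outputs follow the
anterior-positive choice.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field

import numpy as np

from .geometry_io import GeometryError, SurfaceMesh

_ORTHO_TOL = 1e-9


def _unit(v: np.ndarray) -> np.ndarray:
    v = np.asarray(v, dtype=np.float64)
    n = np.linalg.norm(v)
    if n == 0:
        raise GeometryError("zero-length direction")
    return v / n


@dataclass
class OrientationHints:
    """Rough world-space direction guesses used only to fix axis signs."""

    proximal: np.ndarray = field(default_factory=lambda: np.array([0.0, 0.0, 1.0]))
    lateral: np.ndarray = field(default_factory=lambda: np.array([1.0, 0.0, 0.0]))
    anterior: np.ndarray = field(default_factory=lambda: np.array([0.0, 1.0, 0.0]))

    def __post_init__(self) -> None:
        self.proximal = _unit(self.proximal)
        self.lateral = _unit(self.lateral)
        self.anterior = _unit(self.anterior)

    def rotated(self, rotation: np.ndarray) -> "OrientationHints":
        R = np.asarray(rotation)
        return OrientationHints(R @ self.proximal, R @ self.lateral, R @ self.anterior)


@dataclass
class TibialFrame:
    """Orthonormal tibia-based frame: origin + (x_t, y_t, z_t) axes."""

    origin: np.ndarray
    x_t: np.ndarray
    y_t: np.ndarray
    z_t: np.ndarray

    def __post_init__(self) -> None:
        self.origin = np.asarray(self.origin, dtype=np.float64)
        self.x_t = np.asarray(self.x_t, dtype=np.float64)
        self.y_t = np.asarray(self.y_t, dtype=np.float64)
        self.z_t = np.asarray(self.z_t, dtype=np.float64)
        M = self.matrix
        if not np.allclose(M @ M.T, np.eye(3), atol=1e-8):
            raise GeometryError("frame axes are not orthonormal")
        if not np.allclose(np.cross(self.x_t, self.y_t), self.z_t, atol=1e-8):
            raise GeometryError("frame is not right-handed (x_t x y_t != z_t)")

    @property
    def matrix(self) -> np.ndarray:
        """3x3 axes matrix with rows (x_t, y_t, z_t)."""
        return np.vstack([self.x_t, self.y_t, self.z_t])

    # -- serialization: structured text record ------------------------------

    def to_text(self) -> str:
        buf = io.StringIO()
        buf.write("# tibial frame record (mm; rows x_t y_t z_t)\n")
        buf.write("origin: " + " ".join(f"{v:.12g}" for v in self.origin) + "\n")
        for name, ax in zip(("x_t", "y_t", "z_t"), (self.x_t, self.y_t, self.z_t)):
            buf.write(f"{name}: " + " ".join(f"{v:.17g}" for v in ax) + "\n")
        return buf.getvalue()

    @classmethod
    def from_text(cls, text: str) -> "TibialFrame":
        vals: dict[str, np.ndarray] = {}
        for line in text.splitlines():
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            key, _, rest = line.partition(":")
            vals[key.strip()] = np.array([float(t) for t in rest.split()])
        return cls(vals["origin"], vals["x_t"], vals["y_t"], vals["z_t"])


def area_centroid(surface: SurfaceMesh) -> np.ndarray:
    """Area-weighted mean of triangle centroids of a surface mesh (mm)."""
    areas = surface.triangle_areas()
    total = areas.sum()
    if total <= 0:
        raise GeometryError("surface has zero total area")
    return (areas[:, None] * surface.triangle_centroids()).sum(axis=0) / total


def _area_weighted_axes(surface: SurfaceMesh) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Eigen-decomposition of the area-weighted covariance of triangle centroids.

    Returns (eigenvalues ascending, eigenvectors as columns, centroid).
    """
    areas = surface.triangle_areas()
    total = areas.sum()
    if total <= 0:
        raise GeometryError("surface has zero total area")
    cent = surface.triangle_centroids()
    mu = (areas[:, None] * cent).sum(axis=0) / total
    d = cent - mu
    cov = (d * areas[:, None]).T @ d / total
    w, v = np.linalg.eigh(cov)
    return w, v, mu


def build_tibial_frame(
    plateau: SurfaceMesh,
    hints: OrientationHints | None = None,
    circular_tol: float = 1.05,
) -> TibialFrame:
    """Construct the tibia-based frame from the plateau articular surface.

    Parameters
    ----------
    plateau
        Tibial-plateau articular surface mesh (>= 10 vertices spanning 3D).
    hints
        Orientation hints fixing axis signs; defaults to the canonical
        scanner orientation.
    circular_tol
        If the ratio of in-plane principal variances is below this value the
        plateau is treated as near-circular and ``x_t`` falls back to the
        projected lateral hint (deterministic tie-break).
    """
    hints = hints or OrientationHints()
    if len(plateau.vertices) < 10:
        raise GeometryError("plateau mesh has fewer than 10 vertices")
    w, v, _ = _area_weighted_axes(plateau)
    scale = max(w[2], 1e-30)
    if w[1] / scale < 1e-12:
        raise GeometryError("degenerate plateau: vertices are collinear")
    normal = v[:, 0]  # smallest-variance direction
    z_t = normal if normal @ hints.proximal >= 0 else -normal
    if w[2] / max(w[1], 1e-30) < circular_tol:
        # near-circular plateau: in-plane spread does not identify x_t
        lat = hints.lateral - (hints.lateral @ z_t) * z_t
        if np.linalg.norm(lat) < 1e-9:
            raise GeometryError("lateral hint is parallel to the plateau normal")
        x_t = _unit(lat)
    else:
        x_t = v[:, 2]
        if x_t @ hints.lateral < 0:
            x_t = -x_t
    y_t = np.cross(z_t, x_t)
    y_t = _unit(y_t)
    x_t = np.cross(y_t, z_t)  # re-orthogonalize exactly
    return TibialFrame(area_centroid(plateau), x_t, y_t, z_t)
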