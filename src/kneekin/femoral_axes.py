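"""Epicondylar axis by cylinder fitting, condylar reference points, femoral shaft axis.

The posterior femoral condyles are close to a single cylinder over the
flexion arc; the axis of the least-squares cylinder fitted to both condylar
articular surfaces is used as the epicondylar (flexion) axis.  Projecting
the medial and lateral condylar surface centroids onto that axis yields
stable femoral reference points (medial, lateral, and their midpoint, the
femoral centre) that are tracked across acquisitions.

The cylinder fit minimises ``sum((distance-to-axis - r)^2)`` over axis
direction (two spherical angles), axis anchor (2D point in the plane
orthogonal to the direction) and radius, solved by damped least squares
(scipy) initialised from the principal axes of the point cloud.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import least_squares

from .geometry_io import GeometryError, SurfaceMesh
from .tibial_frame import _unit, area_centroid


@dataclass
class Cylinder:
    """Least-squares cylinder: anchor point on axis, unit direction, radius, RMS residual (mm)."""

    point: np.ndarray
    direction: np.ndarray
    radius: float
    rms_residual: float

    def __post_init__(self) -> None:
        self.point = np.asarray(self.point, dtype=np.float64)
        self.direction = _unit(self.direction)
        if self.radius <= 0:
            raise GeometryError("cylinder radius must be positive")
        if self.rms_residual < 0:
            raise GeometryError("negative residual")

    def distance_to_axis(self, points: np.ndarray) -> np.ndarray:
        d = np.atleast_2d(points) - self.point
        along = d @ self.direction
        perp = d - np.outer(along, self.direction)
        return np.linalg.norm(perp, axis=1)

    def project_onto_axis(self, point: np.ndarray) -> np.ndarray:
        """Orthogonal projection of a point onto the cylinder axis."""
        p = np.asarray(point, dtype=np.float64)
        return self.point + ((p - self.point) @ self.direction) * self.direction


@dataclass
class FemoralReferencePoints:
    """Medial/lateral/central femoral reference points on the epicondylar axis."""

    medial: np.ndarray
    lateral: np.ndarray
    central: np.ndarray

    def __post_init__(self) -> None:
        self.medial = np.asarray(self.medial, dtype=np.float64)
        self.lateral = np.asarray(self.lateral, dtype=np.float64)
        self.central = np.asarray(self.central, dtype=np.float64)
        mid = 0.5 * (self.medial + self.lateral)
        if not np.allclose(mid, self.central, atol=1e-6):
            raise GeometryError("central point is not the medial/lateral midpoint")

    def transformed(self, rotation=None, translation=None) -> "FemoralReferencePoints":
        def t(p):
            if rotation is not None:
                p = np.asarray(rotation) @ p
            if translation is not None:
                p = p + np.asarray(translation)
            return p

        return FemoralReferencePoints(t(self.medial), t(self.lateral), t(self.central))


@dataclass
class FemoralLongAxis:
    """Unit direction of the femoral shaft, pointing proximal."""

    direction: np.ndarray

    def __post_init__(self) -> None:
        self.direction = _unit(self.direction)


# ---------------------------------------------------------------------------
# cylinder fitting
# ---------------------------------------------------------------------------


def _direction_from_angles(theta: float, phi: float) -> np.ndarray:
    st, ct = np.sin(theta), np.cos(theta)
    return np.array([st * np.cos(phi), st * np.sin(phi), ct])


def _angles_from_direction(d: np.ndarray) -> tuple[float, float]:
    d = _unit(d)
    return float(np.arccos(np.clip(d[2], -1, 1))), float(np.arctan2(d[1], d[0]))


def _plane_basis(d: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    helper = np.array([1.0, 0.0, 0.0])
    if abs(d @ helper) > 0.9:
        helper = np.array([0.0, 1.0, 0.0])
    e1 = _unit(np.cross(d, helper))
    e2 = np.cross(d, e1)
    return e1, e2


def fit_cylinder(
    points: np.ndarray,
    init_direction: np.ndarray | None = None,
    lateral_hint: np.ndarray | None = None,
    max_nfev: int = 2000,
) -> Cylinder:
    """Least-squares cylinder through a 3D point set.

    Parameters
    ----------
    points
        (n, 3) array, n >= 6, not coplanar.
    init_direction
        Optional axis guess; by default the largest principal direction of
        the point cloud (the condylar patches extend furthest along the
        epicondylar axis).
    lateral_hint
        If given, the returned axis direction is flipped to point
        medial -> lateral (positive dot product with the hint).
    """
    pts = np.asarray(points, dtype=np.float64)
    if pts.ndim != 2 or pts.shape[1] != 3:
        raise GeometryError("points must be (n, 3)")
    if len(pts) < 6:
        raise GeometryError(f"insufficient points for cylinder fit: {len(pts)} < 6")
    mu = pts.mean(axis=0)
    centered = pts - mu
    _, sv, vt = np.linalg.svd(centered, full_matrices=False)
    scale = sv[0]
    if scale == 0 or sv[1] / scale < 1e-9:
        raise GeometryError("points are collinear")
    if sv[2] / scale < 1e-9:
        raise GeometryError("points are coplanar; cylinder fit is ill-posed")

    d0 = _unit(init_direction) if init_direction is not None else vt[0]

    def unpack(x):
        theta, phi, a1, a2, r = x
        d = _direction_from_angles(theta, phi)
        e1, e2 = _plane_basis(d)
        p = mu + a1 * e1 + a2 * e2
        return d, p, r

    def residuals(x):
        d, p, r = unpack(x)
        rel = pts - p
        along = rel @ d
        perp = rel - np.outer(along, d)
        return np.linalg.norm(perp, axis=1) - r

    theta0, phi0 = _angles_from_direction(d0)
    e1, e2 = _plane_basis(d0)
    # crude radius/anchor init: distances from the axis through the centroid
    rel = centered
    perp = rel - np.outer(rel @ d0, d0)
    r0 = max(float(np.linalg.norm(perp, axis=1).mean()), 1e-3)
    x0 = np.array([theta0, phi0, 0.0, 0.0, r0])
    sol = least_squares(
        residuals, x0, method="lm", xtol=1e-15, ftol=1e-15, gtol=1e-15, max_nfev=max_nfev
    )
    if not sol.success:
        raise GeometryError(f"cylinder fit did not converge: {sol.message}")
    d, p, r = unpack(sol.x)
    if r < 0:
        r = -r  # sign of r is a gauge freedom
    if lateral_hint is not None and d @ np.asarray(lateral_hint) < 0:
        d = -d
    rms = float(np.sqrt(np.mean(sol.fun**2)))
    return Cylinder(p, d, float(r), rms)


def condylar_reference_points(
    cylinder: Cylinder,
    medial_surface: SurfaceMesh,
    lateral_surface: SurfaceMesh,
) -> FemoralReferencePoints:
    """Project the condylar surface centroids onto the epicondylar axis."""
    for name, surf in (("medial", medial_surface), ("lateral", lateral_surface)):
        if len(surf.faces) == 0:
            raise GeometryError(f"{name} condylar surface is empty")
    med = cylinder.project_onto_axis(area_centroid(medial_surface))
    lat = cylinder.project_onto_axis(area_centroid(lateral_surface))
    return FemoralReferencePoints(med, lat, 0.5 * (med + lat))


def femoral_long_axis(
    shaft: SurfaceMesh, proximal_hint: np.ndarray | None = None
) -> FemoralLongAxis:
    """First principal direction of the femoral shaft, sign chosen proximal.

    The shaft must be elongated: largest principal extent >= 2x the second.
    """
    if proximal_hint is None:
        proximal_hint = np.array([0.0, 0.0, 1.0])
    v = shaft.vertices
    if len(v) < 4:
        raise GeometryError("shaft mesh too small")
    centered = v - v.mean(axis=0)
    _, sv, vt = np.linalg.svd(centered, full_matrices=False)
    if sv[1] == 0 or sv[0] / sv[1] < 2.0:
        raise GeometryError(
            f"shaft mesh not elongated (principal extent ratio {sv[0] / max(sv[1], 1e-30):.2f} < 2)"
        )
    d = vt[0]
    if d @ np.asarray(proximal_hint) < 0:
        d = -d
    return FemoralLongAxis(d)
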