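"""Patellofemoral kinematics: patella-based frame and the four parameters.

The patella-based coordinate system (PBCS) has its origin at the patellar
centre C (volume centroid of the closed patellar mesh) with

* ``Py`` : longitudinal axis (first principal direction, superior +),
* ``Px`` : medio-lateral axis (second principal direction, lateral +),
* ``Pz = Py x Px`` : anterior axis.

With Px lateral, Py superior and Pz anterior the ordered triple (Px, Py, Pz)
is left-handed; the axis *senses* are what carry meaning and every signed
quantity below states its own convention.  The inferior patellar pole IPP is
the patellar vertex furthest along -Py.

Four parameters are measured per acquisition (axial-view tilt and shift are
the 3D generalisations of the established 2D parameters):

* patellar height — distance from IPP to the tibial medio-lateral axis
  (the line through the tibial origin along x_t), mm;
* patellofemoral angle — angle between Py and the femoral long axis,
  degrees (increases with knee flexion);
* patellar tilt — signed angle, in the PBCS transverse plane, between the
  trochlear facet line Pmin1->Pmin2 and Px; angle open to the medial side
  positive, degrees;
* patellar shift — (C - Pmax) . x_t, lateral positive, mm, where Pmax is
  the trochlear sulcus-floor reference point.

Trochlear landmarks are taken on the section of the trochlea by the PBCS
transverse plane through the patellar centre (the axial slice of the
classic 2D indices): Pmin1 and Pmin2 are the facet peaks of the section
curve, Pmax the posterior-most point of the groove between them.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import trimesh

from .femoral_axes import FemoralLongAxis
from .geometry_io import GeometryError, SurfaceMesh
from .tibial_frame import OrientationHints, TibialFrame, _unit


@dataclass
class PatellarFrame:
    """PBCS: patellar centre C, axes (Px lateral, Py superior, Pz anterior), and IPP."""

    C: np.ndarray
    Px: np.ndarray
    Py: np.ndarray
    Pz: np.ndarray
    IPP: np.ndarray

    def __post_init__(self) -> None:
        self.C = np.asarray(self.C, dtype=np.float64)
        self.IPP = np.asarray(self.IPP, dtype=np.float64)
        self.Px = _unit(self.Px)
        self.Py = _unit(self.Py)
        self.Pz = _unit(self.Pz)
        M = self.matrix
        if not np.allclose(M @ M.T, np.eye(3), atol=1e-8):
            raise GeometryError("patellar axes are not orthonormal")
        if not np.allclose(np.cross(self.Py, self.Px), self.Pz, atol=1e-8):
            raise GeometryError("Pz must equal Py x Px (anterior)")

    @property
    def matrix(self) -> np.ndarray:
        """Rows (Px, Py, Pz): maps world offsets to PBCS coordinates."""
        return np.vstack([self.Px, self.Py, self.Pz])

    def to_local(self, points: np.ndarray) -> np.ndarray:
        return (np.atleast_2d(points) - self.C) @ self.matrix.T


@dataclass
class TrochlearLandmarks:
    """Trochlear reference points (world mm): medial facet, lateral facet, sulcus floor."""

    Pmin1: np.ndarray
    Pmin2: np.ndarray
    Pmax: np.ndarray

    def __post_init__(self) -> None:
        self.Pmin1 = np.asarray(self.Pmin1, dtype=np.float64)
        self.Pmin2 = np.asarray(self.Pmin2, dtype=np.float64)
        self.Pmax = np.asarray(self.Pmax, dtype=np.float64)


@dataclass
class PFParameters:
    """The four patellofemoral parameters of one acquisition."""

    height: float  # mm, >= 0
    pf_angle: float  # degrees
    tilt: float  # degrees, open-to-medial +
    shift: float  # mm, lateral +

    def __post_init__(self) -> None:
        if self.height < 0:
            raise GeometryError("patellar height must be >= 0")
        for v in (self.height, self.pf_angle, self.tilt, self.shift):
            if not np.isfinite(v):
                raise GeometryError("non-finite patellofemoral parameter")


def build_patellar_frame(
    patella: SurfaceMesh, hints: OrientationHints | None = None
) -> PatellarFrame:
    """PBCS from the closed patellar mesh.

    C is the centroid of the enclosed volume (divergence-theorem computation
    on the closed mesh — robust to non-uniform meshing), Py/Px are the
    first/second principal directions of the vertices with signs fixed by
    the superior/lateral hints, and IPP is the vertex minimising (v-C).Py.
    """
    hints = hints or OrientationHints()
    tm = patella.as_trimesh()
    if not tm.is_watertight:
        raise GeometryError("patellar mesh must be closed for the volume centroid")
    C = np.asarray(tm.center_mass, dtype=np.float64)
    v = patella.vertices
    centered = v - v.mean(axis=0)
    cov = centered.T @ centered / len(v)
    w, vecs = np.linalg.eigh(cov)
    if w[1] / max(w[2], 1e-30) < 1e-10:
        raise GeometryError("degenerate patellar principal directions")
    Py = vecs[:, 2]  # largest variance: longitudinal
    Px = vecs[:, 1]
    if Py @ hints.proximal < 0:
        Py = -Py
    if Px @ hints.lateral < 0:
        Px = -Px
    Pz = np.cross(Py, Px)  # anterior
    IPP = v[int(np.argmin((v - C) @ Py))]
    return PatellarFrame(C, Px, Py, Pz, IPP)


def patellar_height(frame: PatellarFrame, tibial: TibialFrame) -> float:
    """Distance (mm) from IPP to the line through the tibial origin along x_t."""
    d = frame.IPP - tibial.origin
    perp = d - (d @ tibial.x_t) * tibial.x_t
    return float(np.linalg.norm(perp))


def patellofemoral_angle(frame: PatellarFrame, femoral_axis: FemoralLongAxis) -> float:
    """Angle (degrees, [0, 180]) between the patellar long axis Py and the femoral axis."""
    c = float(np.clip(frame.Py @ femoral_axis.direction, -1.0, 1.0))
    return float(np.degrees(np.arccos(c)))


def trochlear_landmarks(
    trochlea: SurfaceMesh,
    frame: PatellarFrame,
    rim_fraction: float = 0.2,
    facet_window: float = 25.0,
    fit_halfwidth: float = 6.0,
    snap_to_vertices: bool = False,
) -> TrochlearLandmarks:
    """Trochlear reference points in the PBCS central transverse section.

    The trochlear surface is intersected with the transverse plane of the
    PBCS through the patellar centre (normal Py) — the 3D analogue of the
    axial slice of the classic 2D indices.  The groove shape is then read
    off the section curve in its own in-plane axes (medio-lateral = major
    principal direction, anterior = toward the patella), so detection does
    not degrade for a strongly tilted or laterally displaced patella:

    * the sulcus floor ``Pmax`` is the posterior-most interior point of
      the section (the outer ``rim_fraction`` of the medio-lateral span is
      excluded on each side so the cartilage-label rim cannot masquerade
      as the floor);
    * ``Pmin1`` / ``Pmin2`` are the two facet peaks, up to ``facet_window``
      medial / lateral of the floor, whose connecting line is the
      trochlear reference line of the axial-view tilt; each peak is
      refined by a local parabola fit to the section profile
      (``fit_halfwidth`` around the raw anterior-most point), which keeps
      the peak estimate stable on rough re-extracted surfaces;
    * with ``snap_to_vertices`` the landmarks are moved to the nearest
      trochlear mesh vertices (off by default: the fitted peaks are more
      accurate than any single vertex).

    For a patella riding within the groove, Pmin1 and Pmin2 lie on opposite
    signed-x sides of the PBCS midplane.  Raises :class:`GeometryError`
    when the plane misses the trochlea or a facet set is empty.
    """
    if len(trochlea.vertices) == 0:
        raise GeometryError("empty trochlear mesh")
    segments = trimesh.intersections.mesh_plane(
        trochlea.as_trimesh(), plane_normal=frame.Py, plane_origin=frame.C
    )
    if len(segments) == 0:
        raise GeometryError(
            "patellar transverse plane does not intersect the trochlea"
        )
    pts = segments.reshape(-1, 3)

    # The groove shape is identified in the section's own in-plane axes
    # (medio-lateral = major principal direction, anterior = toward the
    # patella), so that landmark detection does not degrade when the
    # patella is strongly tilted relative to the trochlea.
    mean = pts.mean(axis=0)
    q = pts - mean
    q -= np.outer(q @ frame.Py, frame.Py)
    w_, vecs = np.linalg.eigh(q.T @ q)
    e1 = vecs[:, 2]  # in-plane major axis (medio-lateral)
    if e1 @ frame.Px < 0:
        e1 = -e1
    e2 = np.cross(frame.Py, e1)  # in-plane, orthogonal to e1
    toward_patella = float((frame.C - mean) @ e2)
    if toward_patella < 0:
        e2 = -e2
    u = q @ e1
    anterior = q @ e2
    span = float(u.max() - u.min())
    if span <= 0:
        raise GeometryError("degenerate trochlear section")
    interior = np.flatnonzero(
        (u >= u.min() + rim_fraction * span) & (u <= u.max() - rim_fraction * span)
    )
    if len(interior) == 0:
        raise GeometryError("trochlear section has no interior points")
    imax = interior[int(np.argmin(anterior[interior]))]
    du = u - u[imax]
    medial = np.flatnonzero((du < 0) & (du >= -facet_window))
    lateral = np.flatnonzero((du > 0) & (du <= facet_window))
    if len(medial) == 0 or len(lateral) == 0:
        raise GeometryError(
            "sulcus floor does not split the trochlear section: one facet set is empty"
        )
    def refined_peak(side: np.ndarray) -> np.ndarray:
        i = side[int(np.argmax(anterior[side]))]
        sel = np.flatnonzero(np.abs(u - u[i]) <= fit_halfwidth)
        if len(sel) >= 6:
            coef = np.polyfit(u[sel], anterior[sel], 2)
            if coef[0] < 0:  # concave: a genuine peak
                u_star = float(np.clip(-coef[1] / (2 * coef[0]),
                                       u[i] - fit_halfwidth, u[i] + fit_halfwidth))
                a_star = float(np.polyval(coef, u_star))
                return mean + u_star * e1 + a_star * e2
        return pts[i]

    p1 = refined_peak(medial)
    p2 = refined_peak(lateral)
    pmax = pts[imax]
    chosen = np.stack([p1, p2, pmax])
    if snap_to_vertices:
        verts = trochlea.vertices
        chosen = np.stack([
            verts[int(np.argmin(np.linalg.norm(verts - c, axis=1)))] for c in chosen
        ])
    return TrochlearLandmarks(chosen[0], chosen[1], chosen[2])


def patellar_tilt(landmarks: TrochlearLandmarks, frame: PatellarFrame) -> float:
    """Signed tilt (degrees): angle between Pmin1->Pmin2 and Px in the PBCS transverse plane.

    Positive when the angle opens to the medial side (the patella's medial
    edge rotated anterior relative to the trochlear facet line).
    """
    u = landmarks.Pmin2 - landmarks.Pmin1
    ux = float(u @ frame.Px)
    uz = float(u @ frame.Pz)
    if np.hypot(ux, uz) < 1e-9:
        raise GeometryError("coincident trochlear facet landmarks")
    return float(np.degrees(np.arctan2(uz, ux)))


def patellar_shift(
    frame: PatellarFrame, landmarks: TrochlearLandmarks, tibial: TibialFrame
) -> float:
    """Patellar shift (mm, lateral +): displacement C - Pmax projected on x_t."""
    return float((frame.C - landmarks.Pmax) @ tibial.x_t)


def pf_parameters(
    frame: PatellarFrame,
    landmarks: TrochlearLandmarks,
    tibial: TibialFrame,
    femoral_axis: FemoralLongAxis,
) -> PFParameters:
    """Bundle the four patellofemoral parameters for one acquisition."""
    return PFParameters(
        height=patellar_height(frame, tibial),
        pf_angle=patellofemoral_angle(frame, femoral_axis),
        tilt=patellar_tilt(landmarks, frame),
        shift=patellar_shift(frame, landmarks, tibial),
    )
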