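"""Parametric knee phantom generator with known ground-truth kinematics.

No imaging data ship with the package, so every measurement stage is
validated against synthetic knees: simple parametric femur / tibia /
patella geometries posed with exactly known kinematics, plus cohort
sampling calibrated to the published per-condition means and standard
deviations of the four patellofemoral parameters and to the qualitative
healthy / PCL-deficient tibiofemoral motion patterns.

World frame of the generator (the tibial reference pose): x lateral,
y anterior, z proximal; the tibial plateau surface lies in z = 0 centred
at the origin, so the measured tibial frame is the identity and every
imposed quantity is exact by construction.

Structures
----------
tibia          elliptical slab below the plateau (label 2)
tibial plateau elliptical articular disk at z = 0 (label 4)
condyles       posterior arc patches of a cylinder about the epicondylar
               axis (labels 7 medial / 8 lateral)
femoral shaft  circular cylinder along the flexed femoral axis (label 6)
trochlea       W-profile groove surface extruded along the shaft (label 5)
patella        triaxial ellipsoid lens (label 3)

Posing
------
The condylar complex carries the tibiofemoral dials: imposed medial and
lateral anterior-posterior positions place the epicondylar axis, and the
axial rotation follows as ``asin((lateral - medial) / (2 d))`` with ``d``
the condylar reference-point separation (it is not an independent dial).
The trochlear compartment (shaft, trochlea, patella) is posed by the
flexion angle and the four patellofemoral parameters; it deliberately does
not inherit the axial rotation of the condylar complex so that every
patellofemoral ground-truth value is exact rather than coupled through
landmark selection (a phantom simplification, documented in the methods
note).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import trimesh

from .geometry_io import LABELS, GeometryError, LabelVolume, SurfaceMesh

CONDITIONS = [(f, m) for f in (0, 30, 90) for m in ("relaxed", "active")]

PF_PARAMS = ("height", "pf_angle", "tilt", "shift")

#: Published per-condition calibration (mean, SD) of the four
#: patellofemoral parameters, per group.  Keys: (flexion deg, muscle state).
TABLE1_CALIBRATION: dict[str, dict[str, dict[tuple[int, str], tuple[float, float]]]] = {
    "healthy": {
        "height": {
            (0, "relaxed"): (16.2, 3.8), (0, "active"): (19.7, 4.9),
            (30, "relaxed"): (17.0, 6.3), (30, "active"): (17.2, 3.6),
            (90, "relaxed"): (23.5, 3.2), (90, "active"): (23.7, 7.6),
        },
        "pf_angle": {
            (0, "relaxed"): (5.9, 5.2), (0, "active"): (7.8, 4.6),
            (30, "relaxed"): (21.2, 8.2), (30, "active"): (16.3, 10.8),
            (90, "relaxed"): (49.9, 6.3), (90, "active"): (52.2, 7.8),
        },
        "tilt": {
            (0, "relaxed"): (8.7, 3.4), (0, "active"): (9.7, 4.1),
            (30, "relaxed"): (9.2, 3.9), (30, "active"): (8.2, 2.9),
            (90, "relaxed"): (7.5, 3.5), (90, "active"): (6.4, 6.1),
        },
        "shift": {
            (0, "relaxed"): (1.9, 2.9), (0, "active"): (2.4, 4.6),
            (30, "relaxed"): (1.9, 1.7), (30, "active"): (2.4, 3.3),
            (90, "relaxed"): (4.7, 5.0), (90, "active"): (5.2, 5.0),
        },
    },
    "pcl_deficient": {
        "height": {
            (0, "relaxed"): (15.5, 8.0), (0, "active"): (15.3, 7.7),
            (30, "relaxed"): (17.3, 8.4), (30, "active"): (16.7, 6.9),
            (90, "relaxed"): (21.6, 7.9), (90, "active"): (21.0, 8.2),
        },
        "pf_angle": {
            (0, "relaxed"): (4.3, 4.1), (0, "active"): (7.4, 6.1),
            (30, "relaxed"): (18.9, 6.4), (30, "active"): (17.4, 8.7),
            (90, "relaxed"): (52.3, 4.9), (90, "active"): (51.4, 5.3),
        },
        "tilt": {
            (0, "relaxed"): (9.1, 5.3), (0, "active"): (9.5, 5.7),
            (30, "relaxed"): (9.7, 4.6), (30, "active"): (9.5, 5.2),
            (90, "relaxed"): (13.1, 9.1), (90, "active"): (14.0, 9.4),
        },
        "shift": {
            (0, "relaxed"): (2.1, 1.6), (0, "active"): (3.0, 2.1),
            (30, "relaxed"): (2.4, 2.2), (30, "active"): (3.2, 3.1),
            (90, "relaxed"): (6.7, 5.4), (90, "active"): (6.8, 5.3),
        },
    },
}

#: Default group sizes of the study cohorts.
DEFAULT_GROUP_SIZES = {"healthy": 20, "pcl_deficient": 12}


def loading_torque(mass_kg: float, lever_m: float, g: float = 9.81) -> float:
    """Torque (Nm) of a weight hung at a lever arm: ``mass * g * lever``.

    The study's muscle-active conditions load the shank with 3 kg at
    0.35 m distal to the joint space, i.e. ~10 Nm.
    """
    if mass_kg <= 0 or lever_m <= 0 or g <= 0:
        raise GeometryError("mass, lever arm and g must all be positive")
    return mass_kg * g * lever_m


# ---------------------------------------------------------------------------
# shape and motion parameters
# ---------------------------------------------------------------------------


@dataclass
class KneeShapeParams:
    """Geometric parameters of the parametric knee (all lengths mm)."""

    plateau_semi_ml: float = 35.0
    plateau_semi_ap: float = 25.0
    plateau_half_thickness: float = 0.8
    tibia_depth: float = 12.0
    condyle_radius: float = 20.0
    condyle_offset: float = 18.6          # inner edge of each condylar patch |x|
    condyle_halfwidth: float = 10.0       # patch extent along the axis / 2
    condyle_axis_height: float = 25.0     # epicondylar axis height above plateau
    condyle_arc_deg: tuple[float, float] = (150.0, 260.0)  # posterior-inferior arc
    shaft_radius: float = 12.0
    shaft_length: float = 120.0
    shaft_offset: float = 30.0            # axial gap between condylar centre and shaft
    trochlea_depth: float = 6.0           # groove depth under the facet peaks
    trochlea_peak_offset: float = 16.0    # facet-peak |x|
    trochlea_halflength: float = 18.0     # extrusion half-length along the shaft
    trochlea_clearance: float = 14.0      # patellar centre to groove-floor gap;
                                          # exceeds the patellar AP half-thickness
                                          # plus tilt swing so the rasterised
                                          # patella never erodes the groove shell
    patella_semi_ml: float = 15.0
    patella_semi_ap: float = 8.0
    patella_semi_si: float = 20.0
    ipp_elevation_deg: float = 35.0       # anterior elevation of IPP from vertical
    voxel_spacing: float = 1.0

    def __post_init__(self) -> None:
        lengths = [
            self.plateau_semi_ml, self.plateau_semi_ap, self.plateau_half_thickness,
            self.tibia_depth, self.condyle_radius, self.condyle_offset,
            self.condyle_halfwidth, self.condyle_axis_height, self.shaft_radius,
            self.shaft_length, self.trochlea_depth, self.trochlea_peak_offset,
            self.trochlea_halflength, self.trochlea_clearance, self.patella_semi_ml,
            self.patella_semi_ap, self.patella_semi_si, self.voxel_spacing,
        ]
        if any(v <= 0 for v in lengths):
            raise GeometryError("all shape lengths must be positive")
        if self.trochlea_depth >= self.condyle_radius:
            raise GeometryError("groove depth must be smaller than the condylar radius")

    @property
    def condylar_separation(self) -> float:
        """Distance between the medial and lateral reference points (2 d)."""
        return 2.0 * (self.condyle_offset + self.condyle_halfwidth)

    @property
    def facet_opening_deg(self) -> float:
        """Opening angle of the trochlear groove implied by depth and peak offset."""
        half = math.degrees(math.atan2(self.trochlea_peak_offset, self.trochlea_depth))
        return 2.0 * half


@dataclass
class ConditionKinematics:
    """Imposed kinematic dials for one flexion x muscle condition."""

    medial_ap: float   # mm, anterior +
    lateral_ap: float  # mm, anterior +
    height: float      # mm
    pf_angle: float    # degrees
    tilt: float        # degrees, medial opening +
    shift: float       # mm, lateral +

    def rotation_deg(self, shape: KneeShapeParams) -> float:
        """Implied epicondylar axial rotation (degrees, internal +)."""
        s = (self.lateral_ap - self.medial_ap) / shape.condylar_separation
        if abs(s) >= 1:
            raise GeometryError("condylar AP difference exceeds the condylar separation")
        return math.degrees(math.asin(s))


def _pf_means(group: str, key: tuple[int, str]) -> dict[str, float]:
    cal = TABLE1_CALIBRATION[group]
    return {p: cal[p][key][0] for p in PF_PARAMS}


@dataclass
class MotionModel:
    """Per-condition kinematic dials for one group.

    The default healthy model encodes femoral rollback with larger lateral
    than medial posterior translation and ~10 degrees of external rotation
    over 0->90 degrees, unaffected by flexor activity; the default
    PCL-deficient model matches the healthy one at 0 and 30 degrees but
    shows paradoxical medial-condyle anterior translation (>5 mm from 30 to
    90 degrees, larger under flexor activity) and reduced external
    rotation.  The tibiofemoral magnitudes are package choices (the source
    figures are qualitative); the patellofemoral dials default to the
    published per-condition means.
    """

    group: str
    conditions: dict[tuple[int, str], ConditionKinematics]
    #: enforce the group-level motion pattern (defaults and hand-built group
    #: models); individual cohort draws need not show the mean pattern
    enforce_pattern: bool = True

    def __post_init__(self) -> None:
        missing = [k for k in CONDITIONS if k not in self.conditions]
        if missing:
            raise GeometryError(f"motion model missing conditions: {missing}")
        for key, ck in self.conditions.items():
            for v in (ck.medial_ap, ck.lateral_ap, ck.height, ck.pf_angle, ck.tilt, ck.shift):
                if not np.isfinite(v):
                    raise GeometryError(f"non-finite kinematic value in condition {key}")
        if not self.enforce_pattern:
            return
        if self.group == "pcl_deficient":
            for m in ("relaxed", "active"):
                paradox = (self.conditions[(90, m)].medial_ap
                           - self.conditions[(30, m)].medial_ap)
                if paradox < 5.0:
                    raise GeometryError(
                        "PCL-deficient model must show >= 5 mm medial anterior "
                        f"translation from 30 to 90 degrees ({m}: {paradox:.1f} mm)"
                    )
        if self.group == "healthy":
            for m in ("relaxed", "active"):
                dmed = self.conditions[(90, m)].medial_ap - self.conditions[(0, m)].medial_ap
                dlat = self.conditions[(90, m)].lateral_ap - self.conditions[(0, m)].lateral_ap
                if not dlat < dmed <= 0:
                    raise GeometryError(
                        "healthy model must show posterior translation with "
                        "lateral exceeding medial over 0->90 degrees"
                    )

    @classmethod
    def healthy_default(cls) -> "MotionModel":
        tf = {  # (medial AP, lateral AP) mm, both muscle states identical
            0: (-1.0, 4.0),
            30: (-2.0, -2.0),
            90: (-5.0, -10.0),
        }
        conditions = {}
        for flexion, muscle in CONDITIONS:
            med, lat = tf[flexion]
            conditions[(flexion, muscle)] = ConditionKinematics(
                med, lat, **_pf_means("healthy", (flexion, muscle))
            )
        return cls("healthy", conditions)

    @classmethod
    def pcl_deficient_default(cls) -> "MotionModel":
        tf = {
            (0, "relaxed"): (-1.0, 4.0), (0, "active"): (-1.0, 4.0),
            (30, "relaxed"): (-2.0, -2.0), (30, "active"): (-2.0, -2.0),
            (90, "relaxed"): (4.0, 0.0), (90, "active"): (6.0, 0.0),
        }
        conditions = {}
        for key in CONDITIONS:
            med, lat = tf[key]
            conditions[key] = ConditionKinematics(
                med, lat, **_pf_means("pcl_deficient", key)
            )
        return cls("pcl_deficient", conditions)

    @classmethod
    def default_for(cls, group: str) -> "MotionModel":
        if group == "healthy":
            return cls.healthy_default()
        if group == "pcl_deficient":
            return cls.pcl_deficient_default()
        raise GeometryError(f"unknown group {group!r}")


@dataclass
class GroundTruth:
    """Every kinematic quantity imposed on one generated scene."""

    subject: str
    group: str
    flexion: int
    muscle: str
    medial_ap: float
    lateral_ap: float
    central_ap: float
    rotation: float
    height: float
    pf_angle: float
    tilt: float
    shift: float

    def as_dict(self) -> dict:
        return dict(self.__dict__)


@dataclass
class Scene:
    """One generated subject x condition: per-structure meshes + ground truth."""

    meshes: dict[str, SurfaceMesh]
    ground_truth: GroundTruth
    shape: KneeShapeParams
    volume: LabelVolume | None = None
    geom: dict = field(default_factory=dict, repr=False)


# ---------------------------------------------------------------------------
# mesh construction helpers
# ---------------------------------------------------------------------------


def _grid_mesh(points: np.ndarray, tag: str) -> SurfaceMesh:
    """Triangulate an (nu, nv, 3) structured grid of surface points."""
    nu, nv, _ = points.shape
    idx = np.arange(nu * nv).reshape(nu, nv)
    a = idx[:-1, :-1].ravel()
    b = idx[1:, :-1].ravel()
    c = idx[1:, 1:].ravel()
    d = idx[:-1, 1:].ravel()
    faces = np.concatenate([np.stack([a, b, c], 1), np.stack([a, c, d], 1)])
    return SurfaceMesh(points.reshape(-1, 3), faces, tag)


def _elliptical_disk(a: float, b: float, z: float, tag: str,
                     n_r: int = 6, n_t: int = 48) -> SurfaceMesh:
    """Fan-triangulated elliptical disk with symmetric vertex layout."""
    angles = np.linspace(0, 2 * np.pi, n_t, endpoint=False)
    verts = [np.array([0.0, 0.0, z])]
    rings = []
    for j in range(1, n_r + 1):
        r = j / n_r
        ring = np.stack(
            [a * r * np.cos(angles), b * r * np.sin(angles), np.full(n_t, z)], axis=1
        )
        rings.append(np.arange(len(verts), len(verts) + n_t))
        verts.extend(ring)
    verts = np.asarray(verts)
    faces = []
    first = rings[0]
    for k in range(n_t):
        faces.append([0, first[k], first[(k + 1) % n_t]])
    for j in range(len(rings) - 1):
        inner, outer = rings[j], rings[j + 1]
        for k in range(n_t):
            k2 = (k + 1) % n_t
            faces.append([inner[k], outer[k], outer[k2]])
            faces.append([inner[k], outer[k2], inner[k2]])
    return SurfaceMesh(verts, np.asarray(faces), tag)


def _rot_x(deg: float) -> np.ndarray:
    c, s = math.cos(math.radians(deg)), math.sin(math.radians(deg))
    return np.array([[1, 0, 0], [0, c, -s], [0, s, c]], dtype=float)


def _rot_z(deg: float) -> np.ndarray:
    c, s = math.cos(math.radians(deg)), math.sin(math.radians(deg))
    return np.array([[c, -s, 0], [s, c, 0], [0, 0, 1]], dtype=float)


def _troch_profile(x: np.ndarray, depth: float, xp: float) -> np.ndarray:
    """Anterior height of the W-groove profile: 0 at the floor kink (x=0),
    smooth facet peaks of height ``depth`` at ``x = +-xp``, back to 0 at
    ``|x| = 2 xp``."""
    return depth * np.abs(np.sin(np.pi * x / (2.0 * xp)))


# ---------------------------------------------------------------------------
# scene generation
# ---------------------------------------------------------------------------


def generate_knee(
    shape: KneeShapeParams,
    motion: MotionModel,
    flexion: int,
    muscle: str,
    subject: str = "synthetic",
    voxel_spacing: float | None = None,
) -> Scene:
    """Build one posed knee scene with its ground-truth record.

    Parameters
    ----------
    shape, motion
        Geometry and per-condition kinematic dials.
    flexion, muscle
        Condition key: flexion in {0, 30, 90} degrees, muscle state
        ``"relaxed"`` or ``"active"``.
    voxel_spacing
        If given, additionally rasterise the scene into a label volume at
        this isotropic spacing (mm).
    """
    key = (int(flexion), muscle)
    if key not in motion.conditions:
        raise GeometryError(f"inconsistent condition key {key}")
    ck = motion.conditions[key]
    sp = shape
    meshes: dict[str, SurfaceMesh] = {}
    geom: dict = {}

    # --- tibia + plateau (the fixed reference) -----------------------------
    meshes["tibial_plateau"] = _elliptical_disk(
        sp.plateau_semi_ml, sp.plateau_semi_ap, 0.0, "tibial_plateau"
    )
    tibia = trimesh.creation.cylinder(radius=1.0, height=sp.tibia_depth, sections=48)
    tibia.apply_scale([sp.plateau_semi_ml, sp.plateau_semi_ap, 1.0])
    tibia.apply_translation([0, 0, -sp.tibia_depth / 2])
    meshes["tibia"] = SurfaceMesh(np.asarray(tibia.vertices), np.asarray(tibia.faces), "tibia")
    geom["plateau"] = (sp.plateau_semi_ml, sp.plateau_semi_ap, sp.plateau_half_thickness)
    geom["tibia"] = (sp.plateau_semi_ml, sp.plateau_semi_ap, sp.tibia_depth)

    # --- condylar complex (tibiofemoral dials) -----------------------------
    d = sp.condyle_offset + sp.condyle_halfwidth
    rot = ck.rotation_deg(sp)
    gamma = math.radians(rot)
    y_c = 0.5 * (ck.medial_ap + ck.lateral_ap)
    P0 = np.array([0.0, y_c, sp.condyle_axis_height])
    direction = np.array([math.cos(gamma), math.sin(gamma), 0.0])
    n1 = np.array([-math.sin(gamma), math.cos(gamma), 0.0])  # anterior at gamma=0
    n2 = np.array([0.0, 0.0, 1.0])
    phi = np.radians(np.linspace(*sp.condyle_arc_deg, 23))
    circ = (np.cos(phi)[:, None] * n1 + np.sin(phi)[:, None] * n2) * sp.condyle_radius
    for tag, sign in (("condyle_medial", -1.0), ("condyle_lateral", 1.0)):
        s_lo = sp.condyle_offset
        s_vals = sign * np.linspace(s_lo, s_lo + 2 * sp.condyle_halfwidth, 21)
        pts = (P0[None, None, :]
               + s_vals[:, None, None] * direction[None, None, :]
               + circ[None, :, :])
        meshes[tag] = _grid_mesh(pts, tag)
    geom["condyle"] = dict(
        P0=P0, direction=direction, n1=n1, n2=n2, radius=sp.condyle_radius,
        s_range=(sp.condyle_offset, sp.condyle_offset + 2 * sp.condyle_halfwidth),
        arc_deg=sp.condyle_arc_deg,
    )

    # --- trochlear compartment (flexion + patellofemoral dials) ------------
    # knee flexion swings the femoral proximal end posterior (sitting pose),
    # so the trochlear/anterior aspect rotates up
    theta = math.radians(flexion)
    F = np.array([0.0, -math.sin(theta), math.cos(theta)])     # shaft, proximal
    a_hat = np.array([0.0, math.cos(theta), math.sin(theta)])  # trochlear anterior
    beta = ck.pf_angle
    phi_p = beta - flexion  # patellar long-axis sagittal elevation (anterior +)
    Rsag = _rot_x(-phi_p)
    Rpat = Rsag @ _rot_z(-ck.tilt)
    Py = Rsag @ np.array([0.0, 0.0, 1.0])

    psi = math.radians(sp.ipp_elevation_deg)
    IPP = np.array([ck.shift, ck.height * math.sin(psi), ck.height * math.cos(psi)])
    C = IPP + sp.patella_semi_si * Py

    pat = trimesh.creation.uv_sphere(radius=1.0, count=[24, 24])
    semi = np.array([sp.patella_semi_ml, sp.patella_semi_ap, sp.patella_semi_si])
    pv = np.asarray(pat.vertices) * semi
    pv = pv @ Rpat.T + C
    meshes["patella"] = SurfaceMesh(pv, np.asarray(pat.faces), "patella")
    geom["patella"] = dict(C=C, R=Rpat, semi=semi)

    cosb = math.cos(math.radians(beta))
    tanb = math.tan(math.radians(beta)) if abs(cosb) > 1e-9 else 0.0
    t0 = sp.trochlea_clearance * tanb  # recentres the groove on the patellar slab
    Q0 = np.array([0.0, C[1], C[2]]) - sp.trochlea_clearance * a_hat + t0 * F
    xs = np.linspace(-2 * sp.trochlea_peak_offset, 2 * sp.trochlea_peak_offset, 65)
    ts = np.linspace(-sp.trochlea_halflength, sp.trochlea_halflength, 31)
    prof = _troch_profile(xs, sp.trochlea_depth, sp.trochlea_peak_offset)
    tro = (Q0[None, None, :]
           + xs[:, None, None] * np.array([1.0, 0.0, 0.0])[None, None, :]
           + ts[None, :, None] * F[None, None, :]
           + prof[:, None, None] * a_hat[None, None, :])
    meshes["trochlea"] = _grid_mesh(tro, "trochlea")
    geom["trochlea"] = dict(
        Q0=Q0, g=F, a=a_hat, depth=sp.trochlea_depth, xp=sp.trochlea_peak_offset,
        t_range=(-sp.trochlea_halflength, sp.trochlea_halflength),
    )

    shaft_c = np.array([0.0, 0.0, sp.condyle_axis_height]) \
        + (sp.shaft_offset + sp.shaft_length / 2) * F
    shaft = trimesh.creation.cylinder(radius=sp.shaft_radius, height=sp.shaft_length,
                                      sections=32)
    align = trimesh.geometry.align_vectors([0, 0, 1], F)
    shaft.apply_transform(align)
    shaft.apply_translation(shaft_c)
    meshes["femoral_shaft"] = SurfaceMesh(
        np.asarray(shaft.vertices), np.asarray(shaft.faces), "femoral_shaft"
    )
    geom["shaft"] = dict(center=shaft_c, direction=F, radius=sp.shaft_radius,
                         half_length=sp.shaft_length / 2)

    gt = GroundTruth(
        subject=subject, group=motion.group, flexion=int(flexion), muscle=muscle,
        medial_ap=ck.medial_ap, lateral_ap=ck.lateral_ap,
        central_ap=0.5 * (ck.medial_ap + ck.lateral_ap), rotation=rot,
        # height and patellofemoral angle are unsigned quantities: geometry
        # built from a negative dial realises the absolute value
        height=abs(ck.height), pf_angle=abs(ck.pf_angle),
        tilt=ck.tilt, shift=ck.shift,
    )
    scene = Scene(meshes=meshes, ground_truth=gt, shape=sp, geom=geom)
    if voxel_spacing is not None:
        scene.volume = voxelize_scene(scene, voxel_spacing)
    return scene


# ---------------------------------------------------------------------------
# rasterisation
# ---------------------------------------------------------------------------


def voxelize_scene(scene: Scene, spacing: float, shell: float = 2.0,
                   margin: float = 4.0) -> LabelVolume:
    """Rasterise a scene into an integer label volume.

    Solid structures (tibia, patella, shaft) are filled; articular surfaces
    (plateau, condyles, trochlea) become thin shells of total thickness
    ``shell`` centred on the true surface, so that the 0.5-level isosurface
    straddles the analytic geometry symmetrically and surface re-extraction
    is unbiased.
    """
    if spacing <= 0:
        raise GeometryError("voxel spacing must be positive")
    allv = np.concatenate([m.vertices for m in scene.meshes.values()])
    lo = allv.min(axis=0) - margin
    hi = allv.max(axis=0) + margin
    shape = np.ceil((hi - lo) / spacing).astype(int) + 1
    axes = [lo[i] + spacing * np.arange(shape[i]) for i in range(3)]
    X, Y, Z = np.meshgrid(*axes, indexing="ij")
    P = np.stack([X, Y, Z], axis=-1)
    labels = np.zeros(tuple(shape), dtype=np.int16)
    half = shell / 2.0
    g = scene.geom

    a, b, depth = g["tibia"]
    ell = (X / a) ** 2 + (Y / b) ** 2 <= 1.0
    labels[ell & (Z >= -depth) & (Z <= half)] = LABELS["tibia"]
    a, b, pht = g["plateau"]
    labels[ell & (np.abs(Z) <= max(pht, half))] = LABELS["tibial_plateau"]

    sh = g["shaft"]
    rel = P - sh["center"]
    along = rel @ sh["direction"]
    radial = np.linalg.norm(rel - along[..., None] * sh["direction"], axis=-1)
    labels[(radial <= sh["radius"]) & (np.abs(along) <= sh["half_length"])] = \
        LABELS["femoral_shaft"]

    tr = g["trochlea"]
    rel = P - tr["Q0"]
    u = rel[..., 0]  # x-component: trochlear profile coordinate
    t = rel @ tr["g"]
    w = rel @ tr["a"]
    inside = (np.abs(u) <= 2 * tr["xp"]) & (np.abs(t) <= tr["t_range"][1])
    offset = np.abs(w - _troch_profile(u, tr["depth"], tr["xp"]))
    labels[inside & (offset <= half)] = LABELS["trochlea"]

    cd = g["condyle"]
    rel = P - cd["P0"]
    s = rel @ cd["direction"]
    c1 = rel @ cd["n1"]
    c2 = rel @ cd["n2"]
    radial = np.hypot(c1, c2)
    ang = np.degrees(np.arctan2(c2, c1)) % 360.0
    lo_a, hi_a = cd["arc_deg"]
    in_arc = (ang >= lo_a) & (ang <= hi_a)
    on_shell = np.abs(radial - cd["radius"]) <= half
    s_lo, s_hi = cd["s_range"]
    labels[on_shell & in_arc & (s >= -s_hi) & (s <= -s_lo)] = LABELS["condyle_medial"]
    labels[on_shell & in_arc & (s >= s_lo) & (s <= s_hi)] = LABELS["condyle_lateral"]

    pa = g["patella"]
    rel = (P - pa["C"]) @ pa["R"]  # world -> patella local
    labels[np.linalg.norm(rel / pa["semi"], axis=-1) <= 1.0] = LABELS["patella"]

    return LabelVolume(labels, (spacing,) * 3, tuple(lo))


# ---------------------------------------------------------------------------
# cohort sampling
# ---------------------------------------------------------------------------


@dataclass
class CohortSpec:
    """Sampling specification for one synthetic cohort.

    Defaults follow the study: 20 healthy / 12 PCL-deficient subjects, the
    published per-condition means/SDs for the four patellofemoral
    parameters, and a 2 mm between-subject SD on the condylar AP dials
    (a package choice; the source reports no tibiofemoral spread).
    ``subject_intercept_sd`` adds a shared per-subject random intercept to
    each patellofemoral parameter across conditions (default 0:
    independent draws per condition).
    """

    group: str = "healthy"
    n: int | None = None
    seed: int = 0
    tf_sd: float = 2.0
    subject_intercept_sd: float = 0.0
    calibration: dict | None = None

    def __post_init__(self) -> None:
        if self.group not in DEFAULT_GROUP_SIZES:
            raise GeometryError(f"unknown group {self.group!r}")
        if self.n is None:
            self.n = DEFAULT_GROUP_SIZES[self.group]
        if self.n < 2:
            raise GeometryError("cohort size must be >= 2")
        if self.tf_sd < 0 or self.subject_intercept_sd < 0:
            raise GeometryError("SDs must be >= 0")
        if self.calibration is None:
            self.calibration = TABLE1_CALIBRATION[self.group]
        for p in PF_PARAMS:
            for key in CONDITIONS:
                mean, sd = self.calibration[p][key]
                if sd < 0:
                    raise GeometryError(f"negative SD for {p} at {key}")


@dataclass
class Subject:
    """One sampled subject: a per-subject motion model realisation."""

    subject_id: str
    group: str
    motion: MotionModel


@dataclass
class Cohort:
    """A sampled cohort with its ground-truth table."""

    spec: CohortSpec
    subjects: list[Subject]

    def ground_truth_rows(self) -> list[dict]:
        rows = []
        sp = KneeShapeParams()
        for subj in self.subjects:
            for key in CONDITIONS:
                ck = subj.motion.conditions[key]
                rows.append(dict(
                    subject=subj.subject_id, group=subj.group,
                    flexion=key[0], muscle=key[1],
                    medial_ap=ck.medial_ap, lateral_ap=ck.lateral_ap,
                    central_ap=0.5 * (ck.medial_ap + ck.lateral_ap),
                    rotation=ck.rotation_deg(sp),
                    height=abs(ck.height), pf_angle=abs(ck.pf_angle),
                    tilt=ck.tilt, shift=ck.shift,
                ))
        return rows

    def build_scene(self, subject: Subject, flexion: int, muscle: str,
                    shape: KneeShapeParams | None = None,
                    voxel_spacing: float | None = None) -> Scene:
        return generate_knee(shape or KneeShapeParams(), subject.motion,
                             flexion, muscle, subject=subject.subject_id,
                             voxel_spacing=voxel_spacing)


def sample_cohort(spec: CohortSpec) -> Cohort:
    """Draw a cohort of per-subject kinematic dials (seeded, reproducible).

    For each subject and condition the four patellofemoral parameters are
    drawn from normal distributions with the calibration means/SDs, and the
    condylar AP dials from normals centred on the group's default motion
    model with SD ``spec.tf_sd``.  Scenes are built lazily via
    :meth:`Cohort.build_scene` so large draw-only cohorts stay cheap.
    """
    rng = np.random.default_rng(spec.seed)
    base = MotionModel.default_for(spec.group)
    subjects: list[Subject] = []
    for i in range(spec.n):
        intercepts = {
            p: (rng.normal(0.0, spec.subject_intercept_sd)
                if spec.subject_intercept_sd > 0 else 0.0)
            for p in PF_PARAMS
        }
        conditions: dict[tuple[int, str], ConditionKinematics] = {}
        for key in CONDITIONS:
            ck = base.conditions[key]
            med = rng.normal(ck.medial_ap, spec.tf_sd)
            lat = rng.normal(ck.lateral_ap, spec.tf_sd)
            pf = {}
            for p in PF_PARAMS:
                mean, sd = spec.calibration[p][key]
                pf[p] = rng.normal(mean, sd) + intercepts[p]
            conditions[key] = ConditionKinematics(med, lat, **pf)
        motion = MotionModel(spec.group, conditions, enforce_pattern=False)
        subjects.append(Subject(f"{spec.group[:3]}{i:03d}", spec.group, motion))
    return Cohort(spec, subjects)
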