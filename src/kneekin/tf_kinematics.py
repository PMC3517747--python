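"""Tibiofemoral kinematics: femoral reference points in the tibial frame.

Each acquisition carries its own tibial frame (the tibia is re-segmented
per pose); the femoral reference points are expressed in that frame and
anterior-posterior translation and epicondylar rotation are differenced
between acquisitions.

Sign conventions (fixed package-wide): anterior +y, lateral +x, femoral
internal rotation positive.  The epicondylar rotation is the signed angle,
in the tibial transverse plane, between the projected medial->lateral
condylar vector and x_t; for a right knee a positive angle means the
lateral condyle sits anterior of the medial one, i.e. the femur is
internally rotated.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .femoral_axes import FemoralReferencePoints
from .geometry_io import GeometryError
from .tibial_frame import TibialFrame

FLEXION_LABELS = (0, 30, 90)
MUSCLE_STATES = ("relaxed", "active")
GROUPS = ("healthy", "pcl_deficient")


def express_in_frame(point: np.ndarray, frame: TibialFrame) -> np.ndarray:
    """World point -> local tibial-frame coordinates: ``A (p - origin)``."""
    p = np.asarray(point, dtype=np.float64)
    return frame.matrix @ (p - frame.origin)


def express_in_world(local: np.ndarray, frame: TibialFrame) -> np.ndarray:
    """Inverse of :func:`express_in_frame`."""
    return frame.matrix.T @ np.asarray(local, dtype=np.float64) + frame.origin


def reference_points_in_frame(
    points: FemoralReferencePoints, frame: TibialFrame
) -> FemoralReferencePoints:
    return FemoralReferencePoints(
        express_in_frame(points.medial, frame),
        express_in_frame(points.lateral, frame),
        express_in_frame(points.central, frame),
    )


@dataclass
class PoseSample:
    """Femoral reference points of one subject x condition, in that pose's tibial frame (mm)."""

    subject: str
    group: str
    flexion: int
    muscle: str
    points: FemoralReferencePoints  # local coordinates

    def __post_init__(self) -> None:
        if self.flexion not in FLEXION_LABELS:
            raise GeometryError(f"flexion label must be one of {FLEXION_LABELS}")
        if self.muscle not in MUSCLE_STATES:
            raise GeometryError(f"muscle state must be one of {MUSCLE_STATES}")
        for p in (self.points.medial, self.points.lateral, self.points.central):
            if not np.all(np.isfinite(p)):
                raise GeometryError("non-finite reference point")


def epicondylar_rotation(pose: PoseSample) -> float:
    """Signed epicondylar-axis rotation (degrees, femoral internal rotation +).

    Angle in the tibial transverse plane between the projected
    medial->lateral vector and x_t, in (-180, 180].
    """
    v = pose.points.lateral - pose.points.medial
    vx, vy = float(v[0]), float(v[1])
    planar = np.hypot(vx, vy)
    if planar < 1e-6 * max(np.linalg.norm(v), 1e-12) or planar == 0.0:
        raise GeometryError("epicondylar axis is near-vertical; transverse projection degenerate")
    ang = float(np.degrees(np.arctan2(vy, vx)))
    return _wrap_angle(ang)


def _wrap_angle(deg: float) -> float:
    """Wrap an angle in degrees to (-180, 180]."""
    wrapped = (deg + 180.0) % 360.0 - 180.0
    if wrapped == -180.0:
        wrapped = 180.0
    return wrapped


@dataclass
class TFKinematicsDelta:
    """AP translations (mm, anterior +) and rotation change (deg, internal +) b - a."""

    subject: str
    medial_ap: float
    lateral_ap: float
    central_ap: float
    rotation: float


def tf_delta(pose_a: PoseSample, pose_b: PoseSample) -> TFKinematicsDelta:
    """Tibiofemoral change from pose_a to pose_b (same subject).

    AP translation per reference point is the local y-difference (b - a);
    the rotation change is the epicondylar-rotation difference wrapped to
    (-180, 180].
    """
    if pose_a.subject != pose_b.subject or pose_a.group != pose_b.group:
        raise GeometryError(
            f"pose subject mismatch: {pose_a.subject}/{pose_a.group} vs {pose_b.subject}/{pose_b.group}"
        )
    dmed = float(pose_b.points.medial[1] - pose_a.points.medial[1])
    dlat = float(pose_b.points.lateral[1] - pose_a.points.lateral[1])
    dcen = float(pose_b.points.central[1] - pose_a.points.central[1])
    drot = _wrap_angle(epicondylar_rotation(pose_b) - epicondylar_rotation(pose_a))
    return TFKinematicsDelta(pose_a.subject, dmed, dlat, dcen, drot)
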