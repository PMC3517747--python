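"""Measurement pipeline: segmented geometry in, kinematics records out.

One scene (a subject in one flexion x muscle condition) is measured by:

1. building the tibial frame from the plateau articular surface;
2. fitting the epicondylar cylinder to both posterior condylar surfaces
   jointly and projecting the condylar centroids onto its axis;
3. expressing the reference points in the tibial frame (AP positions and
   epicondylar rotation);
4. building the patellar frame and trochlear landmarks and computing the
   four patellofemoral parameters.

Scenes may come from meshes directly (a mesh-directory convention, one
PLY/STL per structure) or from an integer label volume that is tri-linearly
upsampled and isosurfaced first.
"""

from __future__ import annotations

import math
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .femoral_axes import (condylar_reference_points, femoral_long_axis,
                           fit_cylinder)
from .geometry_io import (LABELS, GeometryError, LabelVolume, SurfaceMesh,
                          extract_surface, trilinear_upsample)
from .pf_kinematics import (build_patellar_frame, pf_parameters,
                            trochlear_landmarks)
from .synthetic_knee import CONDITIONS, Cohort, KneeShapeParams, Scene
from .tf_kinematics import (PoseSample, epicondylar_rotation,
                            reference_points_in_frame)
from .tibial_frame import OrientationHints, build_tibial_frame

#: Structures the measurement stage requires.
REQUIRED_STRUCTURES = (
    "tibial_plateau", "condyle_medial", "condyle_lateral",
    "femoral_shaft", "trochlea", "patella",
)

DELTA_PAIRS = ((0, 30), (30, 90), (0, 90))


@dataclass
class KinematicsRecord:
    """Measured kinematics of one subject x condition."""

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
    cylinder_rms: float

    def as_dict(self) -> dict:
        return asdict(self)


def measure_scene(
    meshes: dict[str, SurfaceMesh],
    subject: str = "unknown",
    group: str = "healthy",
    flexion: int = 0,
    muscle: str = "relaxed",
    hints: OrientationHints | None = None,
) -> KinematicsRecord:
    """Run the full measurement chain on one scene's structure meshes."""
    hints = hints or OrientationHints()
    missing = [s for s in REQUIRED_STRUCTURES if s not in meshes]
    if missing:
        raise GeometryError(f"scene is missing structures: {missing}")

    frame = build_tibial_frame(meshes["tibial_plateau"], hints)
    cyl_points = np.concatenate([
        meshes["condyle_medial"].vertices, meshes["condyle_lateral"].vertices
    ])
    cylinder = fit_cylinder(cyl_points, lateral_hint=frame.x_t)
    refs = condylar_reference_points(
        cylinder, meshes["condyle_medial"], meshes["condyle_lateral"]
    )
    local = reference_points_in_frame(refs, frame)
    pose = PoseSample(subject, group, int(flexion), muscle, local)
    rotation = epicondylar_rotation(pose)

    # the flexed femoral shaft points proximal-posterior (up to horizontal at
    # 90 degrees), so the pure proximal hint would be degenerate there
    shaft_hint = hints.proximal - hints.anterior
    axis = femoral_long_axis(meshes["femoral_shaft"], proximal_hint=shaft_hint)
    pframe = build_patellar_frame(meshes["patella"], hints)
    landmarks = trochlear_landmarks(meshes["trochlea"], pframe)
    pf = pf_parameters(pframe, landmarks, frame, axis)

    return KinematicsRecord(
        subject=subject, group=group, flexion=int(flexion), muscle=muscle,
        medial_ap=float(local.medial[1]), lateral_ap=float(local.lateral[1]),
        central_ap=float(local.central[1]), rotation=rotation,
        height=pf.height, pf_angle=pf.pf_angle, tilt=pf.tilt, shift=pf.shift,
        cylinder_rms=cylinder.rms_residual,
    )


def meshes_from_volume(
    volume: LabelVolume, target_spacing: float = 0.5
) -> dict[str, SurfaceMesh]:
    """Upsample a label volume and isosurface every pipeline structure.

    The integer upsampling factor per axis is chosen to bring the spacing
    at or below ``target_spacing`` (default 0.5 mm isotropic).
    """
    factor = tuple(max(1, math.ceil(s / target_spacing - 1e-9)) for s in volume.spacing)
    fine = trilinear_upsample(volume, factor)
    meshes = {}
    for name in REQUIRED_STRUCTURES:
        meshes[name] = extract_surface(fine, LABELS[name])
    return meshes


def measure_record(scene: Scene, hints: OrientationHints | None = None,
                   from_volume: bool = False,
                   target_spacing: float = 0.5) -> KinematicsRecord:
    """Measure a generated scene, optionally through its voxelised volume."""
    gt = scene.ground_truth
    if from_volume:
        if scene.volume is None:
            raise GeometryError("scene has no label volume")
        meshes = meshes_from_volume(scene.volume, target_spacing)
    else:
        meshes = scene.meshes
    return measure_scene(meshes, subject=gt.subject, group=gt.group,
                         flexion=gt.flexion, muscle=gt.muscle, hints=hints)


def measure_cohort(
    cohort: Cohort,
    shape: KneeShapeParams | None = None,
    conditions: list[tuple[int, str]] | None = None,
    hints: OrientationHints | None = None,
) -> pd.DataFrame:
    """Generate and measure every subject x condition of a cohort (mesh path).

    Degenerate scenes are skipped with a note in the ``error`` column of the
    returned frame rather than aborting the cohort.
    """
    shape = shape or KneeShapeParams()
    rows = []
    for subj in cohort.subjects:
        for key in conditions or CONDITIONS:
            try:
                scene = cohort.build_scene(subj, key[0], key[1], shape=shape)
                rec = measure_record(scene, hints=hints)
                rows.append(rec.as_dict())
            except GeometryError as exc:  # pragma: no cover - robustness path
                rows.append(dict(subject=subj.subject_id, group=subj.group,
                                 flexion=key[0], muscle=key[1], error=str(exc)))
    return pd.DataFrame(rows)


def records_to_deltas(records: pd.DataFrame) -> pd.DataFrame:
    """Tibiofemoral changes between flexion positions, per subject and muscle state."""
    rows = []
    for (subject, group, muscle), sub in records.groupby(["subject", "group", "muscle"]):
        by_flex = {int(r.flexion): r for r in sub.itertuples()}
        for fa, fb in DELTA_PAIRS:
            if fa not in by_flex or fb not in by_flex:
                continue
            a, b = by_flex[fa], by_flex[fb]
            rot = (b.rotation - a.rotation + 180.0) % 360.0 - 180.0
            rows.append(dict(
                subject=subject, group=group, muscle=muscle,
                from_flexion=fa, to_flexion=fb,
                medial_ap=b.medial_ap - a.medial_ap,
                lateral_ap=b.lateral_ap - a.lateral_ap,
                central_ap=b.central_ap - a.central_ap,
                rotation=rot if rot != -180.0 else 180.0,
            ))
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# dataset directory convention
# ---------------------------------------------------------------------------


def condition_dirname(flexion: int, muscle: str) -> str:
    return f"flex{flexion:02d}_{muscle}"


def write_scene(scene: Scene, directory: str | Path) -> list[Path]:
    """Write one scene's meshes (ASCII PLY) and optional volume to a directory."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    written = []
    for name, mesh in scene.meshes.items():
        path = directory / f"{name}.ply"
        mesh.save(path)
        written.append(path)
    if scene.volume is not None:
        from .geometry_io import write_label_volume

        path = directory / "labels.nii.gz"
        write_label_volume(scene.volume, path)
        written.append(path)
    return written


def read_scene_meshes(directory: str | Path) -> dict[str, SurfaceMesh]:
    directory = Path(directory)
    meshes = {}
    for name in REQUIRED_STRUCTURES:
        for ext in (".ply", ".stl"):
            path = directory / f"{name}{ext}"
            if path.exists():
                meshes[name] = SurfaceMesh.load(path, tag=name)
                break
    return meshes
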