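"""Patellar frame, trochlear landmarks, and the four patellofemoral parameters."""

import numpy as np
import pytest
import trimesh

import kneekin as kk
from kneekin.geometry_io import GeometryError
from kneekin.synthetic_knee import ConditionKinematics, MotionModel

from conftest import elliptical_plate, random_rotation


def ellipsoid_mesh(semi=(20.0, 10.0, 25.0)) -> kk.SurfaceMesh:
    """Triaxial ellipsoid: ML 20, AP 10, SI 25 (distinct principal axes)."""
    ball = trimesh.creation.uv_sphere(radius=1.0, count=[24, 24])
    return kk.SurfaceMesh(np.asarray(ball.vertices) * np.asarray(semi),
                          np.asarray(ball.faces))


def scene_with(flexion=90, muscle="relaxed", group="pcl_deficient", **overrides):
    """Default scene with selected patellofemoral dials overridden."""
    motion = MotionModel.default_for(group)
    ck = motion.conditions[(flexion, muscle)]
    fields = dict(medial_ap=ck.medial_ap, lateral_ap=ck.lateral_ap,
                  height=ck.height, pf_angle=ck.pf_angle, tilt=ck.tilt,
                  shift=ck.shift)
    fields.update(overrides)
    motion.conditions[(flexion, muscle)] = ConditionKinematics(**fields)
    return kk.generate_knee(kk.KneeShapeParams(), motion, flexion, muscle)


def test_patellar_frame_canonical_ellipsoid():
    frame = kk.build_patellar_frame(ellipsoid_mesh())
    np.testing.assert_allclose(frame.C, 0.0, atol=1e-9)
    np.testing.assert_allclose(frame.Py, [0, 0, 1], atol=1e-9)
    np.testing.assert_allclose(frame.Px, [1, 0, 0], atol=1e-9)
    np.testing.assert_allclose(frame.Pz, [0, 1, 0], atol=1e-9)  # anterior
    np.testing.assert_allclose(frame.IPP, [0, 0, -25.0], atol=1e-9)


def test_patellar_frame_rotation_equivariance(rng):
    mesh = ellipsoid_mesh()
    base = kk.build_patellar_frame(mesh)
    for _ in range(10):
        R = random_rotation(rng)
        t = rng.uniform(-20, 20, 3)
        frame = kk.build_patellar_frame(
            mesh.transformed(rotation=R, translation=t),
            kk.OrientationHints().rotated(R),
        )
        np.testing.assert_allclose(frame.C, R @ base.C + t, atol=1e-8)
        np.testing.assert_allclose(frame.Py, R @ base.Py, atol=1e-8)
        np.testing.assert_allclose(frame.Px, R @ base.Px, atol=1e-8)
        np.testing.assert_allclose(frame.IPP, R @ base.IPP + t, atol=1e-8)


def test_patellar_frame_orthonormal():
    frame = kk.build_patellar_frame(ellipsoid_mesh())
    M = frame.matrix
    np.testing.assert_allclose(M @ M.T, np.eye(3), atol=1e-9)


def test_open_mesh_rejected():
    mesh = ellipsoid_mesh()
    open_mesh = kk.SurfaceMesh(mesh.vertices, mesh.faces[:-20])
    with pytest.raises(GeometryError, match="closed"):
        kk.build_patellar_frame(open_mesh)


def _frame_with_ipp(ipp):
    frame = kk.build_patellar_frame(ellipsoid_mesh())
    return kk.PatellarFrame(frame.C, frame.Px, frame.Py, frame.Pz, np.asarray(ipp, float))


def test_height_point_on_axis_is_zero():
    tibial = kk.build_tibial_frame(elliptical_plate())
    assert kk.patellar_height(_frame_with_ipp([17.0, 0, 0]), tibial) == pytest.approx(0.0)


def test_height_3_4_5_triangle():
    tibial = kk.build_tibial_frame(elliptical_plate())
    assert kk.patellar_height(_frame_with_ipp([2.0, 3.0, 4.0]), tibial) == pytest.approx(5.0)


def test_height_matches_line_sampling_oracle(rng):
    """Distance to the tibial ML axis agrees with a dense brute-force minimum
    over sampled line points."""
    tibial = kk.build_tibial_frame(elliptical_plate())
    ipp = rng.uniform(-30, 30, 3)
    h = kk.patellar_height(_frame_with_ipp(ipp), tibial)
    ts = np.linspace(-200, 200, 2_000_001)
    line = tibial.origin[None, :] + ts[:, None] * tibial.x_t[None, :]
    brute = np.min(np.linalg.norm(line - ipp, axis=1))
    assert abs(h - brute) <= 1e-6


@pytest.mark.parametrize("angle", [0.0, 30.0, 90.0])
def test_pf_angle_constructed(angle):
    frame = kk.build_patellar_frame(ellipsoid_mesh())
    c, s = np.cos(np.radians(angle)), np.sin(np.radians(angle))
    axis = kk.FemoralLongAxis(np.array([0.0, s, c]))  # rotate away from Py=z
    assert kk.patellofemoral_angle(frame, axis) == pytest.approx(angle, abs=1e-9)


def test_landmarks_symmetric_configuration():
    """Untilted, centred patella over the symmetric groove: facet points
    mirror about the midplane, sulcus floor on the midline, tilt ~ 0."""
    scene = scene_with(flexion=0, group="healthy", tilt=0.0, shift=0.0)
    frame = kk.build_patellar_frame(scene.meshes["patella"])
    lm = kk.trochlear_landmarks(scene.meshes["trochlea"], frame)
    assert lm.Pmin1[0] == pytest.approx(-lm.Pmin2[0], abs=1.0)
    assert abs(lm.Pmax[0]) <= 1.0  # within one vertex spacing of the midline
    assert kk.patellar_tilt(lm, frame) == pytest.approx(0.0, abs=0.5)


def test_landmarks_on_trochlear_surface():
    """All landmarks lie on the trochlear surface (floor is a mesh vertex;
    fitted facet peaks stay within a vertex spacing of the mesh)."""
    scene = scene_with()
    frame = kk.build_patellar_frame(scene.meshes["patella"])
    lm = kk.trochlear_landmarks(scene.meshes["trochlea"], frame)
    verts = scene.meshes["trochlea"].vertices
    for p in (lm.Pmin1, lm.Pmin2, lm.Pmax):
        assert np.min(np.linalg.norm(verts - p, axis=1)) <= 1.5
    lm_snap = kk.trochlear_landmarks(scene.meshes["trochlea"], frame,
                                     snap_to_vertices=True)
    verts = scene.meshes["trochlea"].vertices
    for p in (lm_snap.Pmin1, lm_snap.Pmin2, lm_snap.Pmax):
        assert np.min(np.linalg.norm(verts - p, axis=1)) == pytest.approx(0.0, abs=1e-12)


@pytest.mark.parametrize("imposed", [10.0, -10.0])
def test_tilt_recovery_and_antisymmetry(imposed):
    """A patella rotated about Py by +-10 degrees measures +-10 degrees
    (medial opening positive)."""
    scene = scene_with(tilt=imposed)
    frame = kk.build_patellar_frame(scene.meshes["patella"])
    lm = kk.trochlear_landmarks(scene.meshes["trochlea"], frame)
    assert kk.patellar_tilt(lm, frame) == pytest.approx(imposed, abs=0.5)


def test_tilt_coincident_landmarks_rejected():
    frame = kk.build_patellar_frame(ellipsoid_mesh())
    p = np.array([1.0, 2.0, 3.0])
    with pytest.raises(GeometryError, match="coincident"):
        kk.patellar_tilt(kk.TrochlearLandmarks(p, p, p + frame.Py), frame)


def test_shift_recovery():
    """A 6 mm lateral patellar displacement measures 6.0 +- 0.5 mm."""
    scene = scene_with(shift=6.0)
    frame = kk.build_patellar_frame(scene.meshes["patella"])
    lm = kk.trochlear_landmarks(scene.meshes["trochlea"], frame)
    tibial = kk.build_tibial_frame(scene.meshes["tibial_plateau"])
    assert kk.patellar_shift(frame, lm, tibial) == pytest.approx(6.0, abs=0.5)


def test_shift_invariant_to_inplane_displacement():
    """Shift only sees the x_t component of C - Pmax."""
    tibial = kk.build_tibial_frame(elliptical_plate())
    frame = kk.build_patellar_frame(ellipsoid_mesh())
    lm = kk.TrochlearLandmarks(np.array([-16.0, 0, 0]), np.array([16.0, 0, 0]),
                               np.array([0.0, 0, 0]))
    base = kk.patellar_shift(frame, lm, tibial)
    for d in (tibial.y_t, tibial.z_t, 3.0 * tibial.y_t - 7.0 * tibial.z_t):
        moved = kk.PatellarFrame(frame.C + d, frame.Px, frame.Py, frame.Pz,
                                 frame.IPP + d)
        assert kk.patellar_shift(moved, lm, tibial) == pytest.approx(base, abs=1e-9)


def test_rigid_transform_invariance_of_parameters(rng):
    """All four parameters are invariant under one rigid transform applied to
    every structure simultaneously."""
    scene = scene_with()
    base = kk.measure_record(scene)
    R = random_rotation(rng)
    t = rng.uniform(-50, 50, 3)
    moved = {k: m.transformed(rotation=R, translation=t)
             for k, m in scene.meshes.items()}
    hints = kk.OrientationHints().rotated(R)
    rec = kk.measure_scene(moved, flexion=scene.ground_truth.flexion, hints=hints)
    for k in ("height", "pf_angle", "tilt", "shift", "medial_ap", "lateral_ap",
              "rotation"):
        assert getattr(rec, k) == pytest.approx(getattr(base, k), abs=1e-6)
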