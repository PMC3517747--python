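"""Shared fixtures: canonical meshes, generated scenes, seeded randomness."""

import numpy as np
import pytest

import kneekin as kk


def random_rotation(rng: np.random.Generator) -> np.ndarray:
    """Uniform random rotation matrix (QR of a Gaussian matrix, det +1)."""
    q, r = np.linalg.qr(rng.normal(size=(3, 3)))
    q *= np.sign(np.diag(r))
    if np.linalg.det(q) < 0:
        q[:, 0] = -q[:, 0]
    return q


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20120)


@pytest.fixture(scope="session")
def shape():
    return kk.KneeShapeParams()


@pytest.fixture(scope="session")
def healthy_scene(shape):
    """Healthy default knee at 30 degrees, relaxed (mesh representation)."""
    return kk.generate_knee(shape, kk.MotionModel.healthy_default(), 30, "relaxed")


@pytest.fixture(scope="session")
def voxel_scene_measured(shape):
    """PCL-deficient 90-degree scene rasterised at 1 mm, measured through
    both the mesh path and the volume path (expensive: shared per session)."""
    scene = kk.generate_knee(
        shape, kk.MotionModel.pcl_deficient_default(), 90, "relaxed",
        voxel_spacing=1.0,
    )
    mesh_rec = kk.measure_record(scene)
    voxel_rec = kk.measure_record(scene, from_volume=True)
    return scene, mesh_rec, voxel_rec


def sphere_volume(radius: float, spacing: float, label: int = 2) -> kk.LabelVolume:
    """Voxelised solid sphere centred at the origin (voxel-center convention)."""
    n = int(np.ceil(2 * (radius + 2) / spacing)) + 1
    ax = -(n - 1) / 2 * spacing + spacing * np.arange(n)
    X, Y, Z = np.meshgrid(ax, ax, ax, indexing="ij")
    labels = ((X**2 + Y**2 + Z**2) <= radius**2).astype(np.int16) * label
    return kk.LabelVolume(labels, (spacing,) * 3, (ax[0], ax[0], ax[0]))


def unit_square_plate() -> kk.SurfaceMesh:
    verts = np.array([[0, 0, 0], [1, 0, 0], [1, 1, 0], [0, 1, 0]], dtype=float)
    faces = np.array([[0, 1, 2], [0, 2, 3]])
    return kk.SurfaceMesh(verts, faces)


def elliptical_plate(a=35.0, b=25.0, z=0.0) -> kk.SurfaceMesh:
    from kneekin.synthetic_knee import _elliptical_disk

    return _elliptical_disk(a, b, z, "plate")


def cylinder_points(rng, n=200, radius=20.0, length=60.0,
                    direction=(1.0, 0.0, 0.0), anchor=(0.0, 0.0, 0.0),
                    noise=0.0) -> np.ndarray:
    """Points on (or near) a cylinder surface, for fit oracles."""
    d = np.asarray(direction, dtype=float)
    d /= np.linalg.norm(d)
    helper = np.array([0.0, 0.0, 1.0]) if abs(d[2]) < 0.9 else np.array([1.0, 0.0, 0.0])
    e1 = np.cross(d, helper)
    e1 /= np.linalg.norm(e1)
    e2 = np.cross(d, e1)
    s = rng.uniform(-length / 2, length / 2, n)
    phi = rng.uniform(0, 2 * np.pi, n)
    pts = (np.asarray(anchor)
           + np.outer(s, d)
           + radius * (np.outer(np.cos(phi), e1) + np.outer(np.sin(phi), e2)))
    if noise > 0:
        pts = pts + rng.normal(0, noise, pts.shape)
    return pts
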