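"""Surface extraction, volume-preserving refinement, curvature, geodesics."""

import numpy as np
import pytest
import trimesh

from tectum.phantom import PhantomSpec, make_concentric_spheres
from tectum.surface_model import (
    extract_isosurface,
    geodesic_distances,
    manifold_neighborhood,
    mean_curvature,
    mesh_geometry,
    outward_vertex_normals,
    refine_surface,
)
from tectum.volume_io import LabelVolume


def _ball_volume(radius_mm=10.0, voxel=0.5, margin=4):
    half = int(np.ceil(radius_mm / voxel)) + margin
    n = 2 * half + 1
    ax = (np.arange(n) - half) * voxel
    X, Y, Z = np.meshgrid(ax, ax, ax, indexing="ij")
    data = (np.sqrt(X**2 + Y**2 + Z**2) < radius_mm).astype(np.int16)
    affine = np.eye(4)
    affine[:3, :3] *= voxel
    affine[:3, 3] = -half * voxel
    return LabelVolume(data=data, affine=affine)


@pytest.fixture(scope="module")
def ball_mesh():
    return extract_isosurface(_ball_volume(), 1)


class TestExtract:
    def test_sphere_radius_and_closure(self, ball_mesh):
        assert ball_mesh.is_watertight
        r = np.linalg.norm(ball_mesh.vertices, axis=1)
        assert np.all(np.abs(r - 10.0) < 0.5)

    def test_enclosed_volume_vs_analytic(self, ball_mesh):
        # divergence-theorem volume against (4/3) pi R^3
        analytic = 4.0 / 3.0 * np.pi * 10.0**3
        assert abs(ball_mesh.volume - analytic) / analytic < 0.02

    def test_empty_label_errors(self):
        vol = _ball_volume()
        with pytest.raises(ValueError, match="empty"):
            extract_isosurface(vol, 3)

    def test_boundary_touch_errors(self):
        data = np.ones((12, 12, 12), dtype=np.int16)
        vol = LabelVolume(data=data, affine=np.eye(4))
        with pytest.raises(ValueError, match="boundary"):
            extract_isosurface(vol, 1)


class TestRefine:
    def test_zero_iterations_identity(self, ball_mesh):
        out = refine_surface(ball_mesh, 0)
        np.testing.assert_array_equal(out.vertices, ball_mesh.vertices)

    def test_volume_preserved_and_smoother(self, ball_mesh):
        out = refine_surface(ball_mesh, 5)
        assert abs(out.volume - ball_mesh.volume) / ball_mesh.volume < 0.005
        r_in = np.linalg.norm(ball_mesh.vertices, axis=1)
        r_out = np.linalg.norm(out.vertices, axis=1)
        assert r_out.std() < r_in.std()

    def test_cube_corners_rounded_volume_kept(self):
        data = np.zeros((24, 24, 24), dtype=np.int16)
        data[4:20, 4:20, 4:20] = 1
        cube = extract_isosurface(LabelVolume(data=data, affine=np.eye(4)), 1)
        out = refine_surface(cube, 5)
        assert abs(out.volume - cube.volume) / cube.volume < 0.005
        # corners round out: the high-curvature tail shrinks (faces bow
        # slightly to preserve volume, so the mean is not informative)
        assert np.percentile(np.abs(mean_curvature(out)), 95) < np.percentile(
            np.abs(mean_curvature(cube)), 95
        )

    def test_open_mesh_rejected(self):
        tri = trimesh.Trimesh(
            vertices=[[0, 0, 0], [1, 0, 0], [0, 1, 0]], faces=[[0, 1, 2]]
        )
        with pytest.raises(ValueError, match="manifold"):
            refine_surface(tri, 5)


class TestCurvature:
    def test_sphere_curvature_one_over_r(self):
        mesh = trimesh.creation.icosphere(3, radius=10.0)
        H = mean_curvature(mesh)
        assert np.all(np.abs(H - 0.1) < 0.015)  # +1/R within 15%

    def test_plane_patch_flat(self):
        # interior of a flat triangulated grid
        n = 12
        xs, ys = np.meshgrid(np.arange(n), np.arange(n), indexing="ij")
        verts = np.column_stack([xs.ravel(), ys.ravel(), np.zeros(n * n)])
        faces = []
        for i in range(n - 1):
            for j in range(n - 1):
                a = i * n + j
                faces.append([a, a + 1, a + n])
                faces.append([a + 1, a + n + 1, a + n])
        mesh = trimesh.Trimesh(vertices=verts, faces=faces, process=False)
        H = mean_curvature(mesh)
        interior = (
            (verts[:, 0] > 0) & (verts[:, 0] < n - 1)
            & (verts[:, 1] > 0) & (verts[:, 1] < n - 1)
        )
        assert np.abs(H[interior]).max() < 1e-6

    def test_saddle_sign_and_magnitude(self):
        # z = (x^2 - y^2)/2: principal curvatures +-1 at the origin, mean ~ 0
        n = 21
        xs, ys = np.meshgrid(
            np.linspace(-1, 1, n), np.linspace(-1, 1, n), indexing="ij"
        )
        zs = 0.5 * (xs**2 - ys**2)
        verts = np.column_stack([xs.ravel(), ys.ravel(), zs.ravel()])
        faces = []
        for i in range(n - 1):
            for j in range(n - 1):
                a = i * n + j
                faces.append([a, a + 1, a + n])
                faces.append([a + 1, a + n + 1, a + n])
        mesh = trimesh.Trimesh(vertices=verts, faces=faces, process=False)
        H = mean_curvature(mesh)
        center = n * (n // 2) + n // 2
        assert abs(H[center]) < 0.5  # |mean| well below both principal magnitudes

    def test_mesh_geometry_fills_metadata(self):
        mesh = trimesh.creation.icosphere(2, radius=5.0)
        out = mesh_geometry(mesh)
        assert out.metadata["outward_normals"].shape == (len(mesh.vertices), 3)
        assert out.metadata["mean_curvature"].shape == (len(mesh.vertices),)


class TestNormals:
    def test_normals_outward_on_phantom_surface(self, sphere_small):
        dm = sphere_small["dm"]
        n = outward_vertex_normals(dm.s1)
        r = np.linalg.norm(dm.s1.vertices, axis=1)
        radial = dm.s1.vertices / r[:, None]
        # stepping along the normal must leave the segmentation
        frac_out = np.mean(np.einsum("ij,ij->i", n, radial) > 0)
        assert frac_out >= 0.99


class TestManifoldNeighborhood:
    def _grid_mesh(self, n=15, edge=1.0):
        xs, ys = np.meshgrid(np.arange(n) * edge, np.arange(n) * edge, indexing="ij")
        verts = np.column_stack([xs.ravel(), ys.ravel(), np.zeros(n * n)])
        faces = []
        for i in range(n - 1):
            for j in range(n - 1):
                a = i * n + j
                faces.append([a, a + 1, a + n])
                faces.append([a + 1, a + n + 1, a + n])
        return trimesh.Trimesh(vertices=verts, faces=faces, process=False)

    def test_tiny_radius_returns_seed_only(self):
        mesh = self._grid_mesh()
        nb = manifold_neighborhood(mesh, 0, 0.5)
        assert nb == {0: 0.0}

    def test_flat_grid_disk_membership(self):
        mesh = self._grid_mesh()
        seed = 7 * 15 + 7
        nb = manifold_neighborhood(mesh, seed, 2.5)
        got = set(nb)
        center = mesh.vertices[seed]
        euclid = np.linalg.norm(mesh.vertices - center, axis=1)
        # the edge graph overestimates distances, so the neighborhood is a
        # subset of the Euclidean disk and contains the disk one edge smaller
        assert got <= set(np.nonzero(euclid <= 2.5 + 1e-9)[0])
        assert set(np.nonzero(euclid <= 1.5)[0]) <= got

    def test_sphere_antipodal_distance(self):
        mesh = trimesh.creation.icosphere(4, radius=10.0)
        seed = 0
        anti = int(np.argmax(np.linalg.norm(mesh.vertices - mesh.vertices[seed], axis=1)))
        dist = geodesic_distances(mesh, [seed])
        assert abs(dist[anti] - np.pi * 10.0) / (np.pi * 10.0) < 0.05

    def test_seed_out_of_range(self):
        mesh = trimesh.creation.icosphere(1)
        with pytest.raises(IndexError):
            manifold_neighborhood(mesh, 10**6, 1.0)
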