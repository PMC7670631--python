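"""Triangulated reference surfaces and their geometry.

Builds the outer brainstem/CSF surface (S1) and the cerebral-aqueduct
surface (S2) from label volumes by isosurfacing, reduces voxelation
artifacts with a volume-preserving smoothing refinement, and provides the
mesh geometry consumed downstream: outward unit normals, per-vertex mean
curvature, and geodesic ("manifold") neighborhoods on the mesh.

Meshes are `trimesh.Trimesh` objects with vertices in world mm; the surface
role (S1, S2, S_PAG, S_ellipse, S_1A) is carried in ``mesh.metadata["role"]``.

Curvature sign convention: a sphere meshed with outward normals has positive
mean curvature 1/R; concave grooves seen from outside are negative.  The
landmarking code can flip this via its ``curvature_sign`` argument.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import trimesh
from scipy import sparse
from scipy.sparse.csgraph import dijkstra
from skimage import measure

from tectum.volume_io import LabelVolume, ScalarVolume, Volume


def _as_float_field(vol: Volume, level) -> tuple[np.ndarray, float]:
    """Return (float field, iso level) for marching cubes.

    Label regions are isosurfaced at the zero level of their signed
    Euclidean distance transform rather than the raw binary mask, which
    places the boundary sub-voxel-accurately and strongly reduces
    staircase artifacts before refinement.
    """
    if isinstance(vol, LabelVolume):
        from scipy.ndimage import distance_transform_edt

        labels = (level,) if np.isscalar(level) else tuple(level)
        mask = np.isin(vol.data, np.asarray(labels, dtype=int))
        if not mask.any():
            raise ValueError(f"label(s) {labels} empty")
        spacing = tuple(vol.voxel_size)
        sdt = distance_transform_edt(mask, sampling=spacing) - distance_transform_edt(
            ~mask, sampling=spacing
        )
        return sdt, 0.0
    return np.asarray(vol.data, dtype=float), float(level)


def extract_isosurface(vol: Volume, level) -> trimesh.Trimesh:
    """Isosurface a label region or scalar threshold, in world mm.

    For a label volume ``level`` is a label id or a tuple of ids whose
    union forms the enclosed region (the outer brainstem surface S1 is the
    boundary of all tissue labels, aqueduct included, while S2 is the
    boundary of the aqueduct label alone).  The region must be non-empty
    and must not touch the grid boundary (pad the volume otherwise); the
    returned mesh is a closed manifold with outward normals.
    """
    field, iso = _as_float_field(vol, level)
    region = field > iso
    if not region.any():
        raise ValueError("thresholded region is empty")
    for axis in range(3):
        first = np.take(region, 0, axis=axis)
        last = np.take(region, -1, axis=axis)
        if first.any() or last.any():
            raise ValueError(
                "region touches the grid boundary; pad the volume before "
                "surfacing so the mesh can close"
            )
    verts, faces, _, _ = measure.marching_cubes(field, level=iso)
    verts = verts @ vol.affine[:3, :3].T + vol.affine[:3, 3]
    mesh = trimesh.Trimesh(vertices=verts, faces=faces, process=True)
    _orient_outward(mesh)
    return mesh


def _orient_outward(mesh: trimesh.Trimesh) -> None:
    """Make winding consistent with outward normals (positive volume)."""
    if not mesh.is_winding_consistent:
        trimesh.repair.fix_normals(mesh)
    if mesh.volume < 0:
        mesh.invert()


def _uniform_laplacian(mesh: trimesh.Trimesh) -> sparse.csr_matrix:
    """Row-normalized vertex adjacency (umbrella operator)."""
    edges = mesh.edges_unique
    n = len(mesh.vertices)
    i = np.concatenate([edges[:, 0], edges[:, 1]])
    j = np.concatenate([edges[:, 1], edges[:, 0]])
    A = sparse.csr_matrix((np.ones(len(i)), (i, j)), shape=(n, n))
    deg = np.asarray(A.sum(axis=1)).ravel()
    deg[deg == 0] = 1.0
    return sparse.diags(1.0 / deg) @ A


def refine_surface(
    mesh: trimesh.Trimesh, iterations: int = 5, relaxation: float = 0.5
) -> trimesh.Trimesh:
    """Reduce voxelation artifacts while preserving enclosed volume.

    Each iteration applies one umbrella (curvature-flow style) smoothing
    step followed by a global rescaling about the centroid that restores the
    enclosed volume exactly, so the net volume drift over any number of
    iterations is only floating-point noise.
    """
    if iterations < 0:
        raise ValueError("iterations must be >= 0")
    if not mesh.is_watertight:
        raise ValueError("refine_surface requires a closed manifold mesh")
    out = mesh.copy()
    if iterations == 0:
        return out
    lap = _uniform_laplacian(out)
    v0 = abs(out.volume)
    verts = out.vertices.copy()
    for _ in range(iterations):
        verts = verts + relaxation * (lap @ verts - verts)
        out.vertices = verts
        c = out.vertices.mean(axis=0)
        scale = (v0 / abs(out.volume)) ** (1.0 / 3.0)
        verts = c + (verts - c) * scale
        out.vertices = verts
    _orient_outward(out)
    return out


def _cotangent_weights(mesh: trimesh.Trimesh) -> sparse.csr_matrix:
    """Symmetric cotangent weight matrix over mesh edges."""
    n = len(mesh.vertices)
    tris = mesh.faces
    V = mesh.vertices
    rows, cols, vals = [], [], []
    for k in range(3):
        a = tris[:, k]
        b = tris[:, (k + 1) % 3]
        c = tris[:, (k + 2) % 3]
        # cotangent of the angle at vertex a, opposite edge (b, c)
        u = V[b] - V[a]
        w = V[c] - V[a]
        cross = np.cross(u, w)
        area2 = np.linalg.norm(cross, axis=1)
        if np.any(area2 < 1e-14):
            bad = np.nonzero(area2 < 1e-14)[0]
            raise ValueError(f"degenerate (zero-area) triangles: {bad.tolist()[:20]}")
        cot = (u * w).sum(axis=1) / area2
        rows.extend([b, c])
        cols.extend([c, b])
        vals.extend([cot, cot])
    rows = np.concatenate(rows)
    cols = np.concatenate(cols)
    vals = 0.5 * np.concatenate(vals)
    return sparse.csr_matrix((vals, (rows, cols)), shape=(n, n))


def mean_curvature(mesh: trimesh.Trimesh) -> np.ndarray:
    """Per-vertex mean curvature (1/mm), sphere-positive for outward normals.

    Uses the cotangent Laplace-Beltrami mean-curvature normal with
    barycentric vertex areas; the sign is taken from the projection onto the
    outward vertex normal.
    """
    W = _cotangent_weights(mesh)
    V = mesh.vertices
    n = len(V)
    deg = np.asarray(W.sum(axis=1)).ravel()
    # W_ij = (cot a + cot b)/2, so (1/(2A_i)) sum_j W_ij (x_i - x_j)
    # equals the mean-curvature normal H_i n_i (outward for convex)
    Kvec = (sparse.diags(deg) @ V - W @ V)
    area = np.zeros(n)
    tri_area = mesh.area_faces
    for k in range(3):
        np.add.at(area, mesh.faces[:, k], tri_area / 3.0)
    Kvec = Kvec / (2.0 * area[:, None])
    normals = outward_vertex_normals(mesh)
    return (Kvec * normals).sum(axis=1)


def outward_vertex_normals(mesh: trimesh.Trimesh) -> np.ndarray:
    """Unit vertex normals pointing away from the enclosed region."""
    _orient_outward(mesh)
    normals = np.array(mesh.vertex_normals, dtype=float)
    norms = np.linalg.norm(normals, axis=1, keepdims=True)
    norms[norms == 0] = 1.0
    return normals / norms


def mesh_geometry(mesh: trimesh.Trimesh) -> trimesh.Trimesh:
    """Fill unit outward normals and per-vertex mean curvature.

    Results are stored as ``mesh.metadata["outward_normals"]`` and
    ``mesh.metadata["mean_curvature"]`` and also returned on the mesh.
    """
    mesh.metadata["outward_normals"] = outward_vertex_normals(mesh)
    mesh.metadata["mean_curvature"] = mean_curvature(mesh)
    return mesh


def edge_graph(mesh: trimesh.Trimesh, two_ring: bool = True) -> sparse.csr_matrix:
    """Sparse symmetric graph for geodesic distances (weights in mm).

    With ``two_ring`` (default) each vertex is additionally connected to
    its two-ring neighborhood by Euclidean chords, which cuts the
    overestimation bias of pure edge-graph shortest paths from ~6% to
    about 2% on curved surfaces.
    """
    edges = mesh.edges_unique
    n = len(mesh.vertices)
    adj = sparse.csr_matrix(
        (np.ones(len(edges)), (edges[:, 0], edges[:, 1])), shape=(n, n)
    )
    adj = adj + adj.T
    if two_ring:
        adj = adj @ adj + adj
    adj = sparse.triu(adj.tocoo(), k=1).tocoo()
    i, j = adj.row, adj.col
    w = np.linalg.norm(mesh.vertices[i] - mesh.vertices[j], axis=1)
    return sparse.csr_matrix(
        (np.concatenate([w, w]), (np.concatenate([i, j]), np.concatenate([j, i]))),
        shape=(n, n),
    )


def geodesic_distances(
    mesh: trimesh.Trimesh,
    seeds: np.ndarray,
    limit: float = np.inf,
    graph: sparse.csr_matrix | None = None,
) -> np.ndarray:
    """Geodesic distance (edge-graph shortest path) from a seed set.

    Returns the minimum distance from any seed to every vertex; vertices
    beyond ``limit`` are ``inf``.
    """
    if graph is None:
        graph = edge_graph(mesh)
    seeds = np.atleast_1d(np.asarray(seeds, dtype=int))
    if seeds.min() < 0 or seeds.max() >= len(mesh.vertices):
        raise IndexError("seed vertex id out of range")
    return dijkstra(graph, indices=seeds, min_only=True, limit=limit)


def manifold_neighborhood(
    mesh: trimesh.Trimesh,
    seed: int,
    radius: float,
    graph: sparse.csr_matrix | None = None,
) -> dict[int, float]:
    """Vertices within ``radius`` mm of geodesic distance from ``seed``.

    Distances are shortest paths on the edge graph; at the sub-millimetre
    radii used for depth kernels the edge-graph error is far below the voxel
    size.
    """
    if radius <= 0:
        raise ValueError("radius must be > 0")
    if not (0 <= seed < len(mesh.vertices)):
        raise IndexError(f"seed {seed} out of range")
    dist = geodesic_distances(mesh, [seed], limit=radius, graph=graph)
    idx = np.nonzero(np.isfinite(dist))[0]
    return {int(i): float(dist[i]) for i in idx if dist[i] <= radius}


def save_mesh(mesh: trimesh.Trimesh, path: str | Path) -> None:
    """Export as PLY or OBJ by extension."""
    mesh.export(str(path))


def load_mesh(path: str | Path) -> trimesh.Trimesh:
    mesh = trimesh.load(str(path), force="mesh")
    _orient_outward(mesh)
    return mesh
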