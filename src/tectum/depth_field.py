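"""Signed Euclidean distance fields and the normalized level-set depth w.

Two signed distance volumes are computed against the reference surfaces:
d1 from the brainstem surface S1 and d2 from the aqueduct surface S2, each
positive for voxels enclosed by its surface and negative outside.  The
normalized depth coordinate solves the algebraic level-set relation

    (1 - w) d1 + w d2 = 0   =>   w = d1 / (d1 - d2)

so w = 0 on S1, w = 1 on S2, w < 0 outside the brainstem and w > 1 inside
the aqueduct.  Distances are exact nearest-point-on-triangle distances; the
spatial index only prunes candidate triangles and never changes the result.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import trimesh
from skimage import measure

from tectum._tridist import TriangleGrid

from tectum.volume_io import ScalarVolume, Volume

#: voxels where |d1 - d2| falls below this are masked invalid (mm)
SINGULARITY_TOL = 1e-6


def point_triangle_distance(
    p: np.ndarray, tri: np.ndarray
) -> tuple[float, np.ndarray]:
    """Exact unsigned distance from a point to one triangle, and the foot.

    ``tri`` is a (3, 3) array of vertices.  Raises on degenerate triangles.
    """
    tri = np.asarray(tri, dtype=float)
    if np.linalg.norm(np.cross(tri[1] - tri[0], tri[2] - tri[0])) < 1e-14:
        raise ValueError("degenerate triangle")
    closest = _closest_point_on_triangles(
        np.asarray(p, dtype=float)[None, :], tri[None, :, :]
    )[0]
    return float(np.linalg.norm(p - closest)), closest


def _closest_point_on_triangles(p: np.ndarray, tri: np.ndarray) -> np.ndarray:
    """Vectorized closest point on triangle (Ericson's region algorithm).

    ``p`` is (n, 3), ``tri`` is (n, 3, 3); one triangle per point.
    """
    a, b, c = tri[:, 0], tri[:, 1], tri[:, 2]
    ab = b - a
    ac = c - a
    ap = p - a
    d1 = np.einsum("ij,ij->i", ab, ap)
    d2 = np.einsum("ij,ij->i", ac, ap)
    bp = p - b
    d3 = np.einsum("ij,ij->i", ab, bp)
    d4 = np.einsum("ij,ij->i", ac, bp)
    cp = p - c
    d5 = np.einsum("ij,ij->i", ab, cp)
    d6 = np.einsum("ij,ij->i", ac, cp)

    out = np.empty_like(p)
    done = np.zeros(len(p), dtype=bool)

    def settle(mask, value):
        new = mask & ~done
        out[new] = value[new]
        done[new] = True

    settle((d1 <= 0) & (d2 <= 0), a)  # vertex a
    settle((d3 >= 0) & (d4 <= d3), b)  # vertex b
    vc = d1 * d4 - d3 * d2
    with np.errstate(divide="ignore", invalid="ignore"):
        v_ab = np.where(d1 - d3 != 0, d1 / (d1 - d3), 0.0)
    settle((vc <= 0) & (d1 >= 0) & (d3 <= 0), a + v_ab[:, None] * ab)  # edge ab
    settle((d6 >= 0) & (d5 <= d6), c)  # vertex c
    vb = d5 * d2 - d1 * d6
    with np.errstate(divide="ignore", invalid="ignore"):
        v_ac = np.where(d2 - d6 != 0, d2 / (d2 - d6), 0.0)
    settle((vb <= 0) & (d2 >= 0) & (d6 <= 0), a + v_ac[:, None] * ac)  # edge ac
    va = d3 * d6 - d5 * d4
    num = d4 - d3
    den = (d4 - d3) + (d5 - d6)
    with np.errstate(divide="ignore", invalid="ignore"):
        v_bc = np.where(den != 0, num / den, 0.0)
    settle(
        (va <= 0) & (d4 - d3 >= 0) & (d5 - d6 >= 0), b + v_bc[:, None] * (c - b)
    )  # edge bc
    denom = va + vb + vc
    with np.errstate(divide="ignore", invalid="ignore"):
        v = np.where(denom != 0, vb / denom, 1 / 3)
        w = np.where(denom != 0, vc / denom, 1 / 3)
    settle(np.ones(len(p), dtype=bool), a + v[:, None] * ab + w[:, None] * ac)
    return out


class _MeshDistance:
    """Exact nearest-triangle queries on a triangle spatial grid.

    The uniform-grid index only prunes candidate triangles with a provable
    early-termination bound; the returned distances equal an exhaustive
    nearest-triangle scan.
    """

    def __init__(self, mesh: trimesh.Trimesh):
        self.mesh = mesh
        self.triangles = np.asarray(mesh.triangles, dtype=float)
        self._grid = TriangleGrid(self.triangles)

    def query(
        self, points: np.ndarray
    ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Return (distance, closest point, triangle index) per point."""
        return self._grid.query(points)


@dataclass
class SignedDistanceField:
    """Signed distance volume, enclosed-positive, in mm."""

    volume: ScalarVolume
    reference: str = "S1"  # S1 | S2

    @property
    def data(self) -> np.ndarray:
        return self.volume.data

    @property
    def affine(self) -> np.ndarray:
        return self.volume.affine


@dataclass
class NormalizedDepthField:
    """Dimensionless level-set depth w with a validity mask."""

    volume: ScalarVolume
    valid: np.ndarray

    @property
    def data(self) -> np.ndarray:
        return self.volume.data

    @property
    def affine(self) -> np.ndarray:
        return self.volume.affine


def _evaluation_mask(grid: Volume, mesh: trimesh.Trimesh, margin_voxels: int) -> np.ndarray:
    """Voxels within the mesh bounding box padded by a voxel margin."""
    lo_w, hi_w = mesh.bounds
    corners = np.array(
        [[x, y, z] for x in (lo_w[0], hi_w[0]) for y in (lo_w[1], hi_w[1]) for z in (lo_w[2], hi_w[2])]
    )
    ijk = grid.world_to_voxel(corners)
    lo = np.floor(ijk.min(axis=0)).astype(int) - margin_voxels
    hi = np.ceil(ijk.max(axis=0)).astype(int) + margin_voxels
    lo = np.maximum(lo, 0)
    hi = np.minimum(hi, np.array(grid.shape) - 1)
    mask = np.zeros(grid.shape, dtype=bool)
    mask[lo[0] : hi[0] + 1, lo[1] : hi[1] + 1, lo[2] : hi[2] + 1] = True
    return mask


def signed_distance_field(
    mesh: trimesh.Trimesh,
    grid: Volume,
    inside: np.ndarray,
    reference: str = "S1",
    margin_voxels: int = 8,
    check_consistency: bool = True,
    eval_mask: np.ndarray | None = None,
) -> SignedDistanceField:
    """Per-voxel signed distance to the nearest mesh triangle (mm).

    Parameters
    ----------
    mesh : closed reference surface in world mm
    grid : any volume supplying the target grid and affine
    inside : boolean voxel mask of the region enclosed by the surface;
        drives the sign (enclosed-positive).  Voxels within half a voxel
        diagonal of the zero level take their sign from the nearest-triangle
        normal instead, which is robust to surface-refinement drift.
    margin_voxels : distances are evaluated inside the mesh bounding box
        padded by this many voxels; voxels beyond are NaN.
    eval_mask : explicit evaluation region overriding the bounding-box rule
        (the two fields entering the level-set ratio must share a region,
        so pair computations pass the outer surface's padded box to both).
    """
    inside = np.asarray(inside, dtype=bool)
    if inside.shape != tuple(grid.shape):
        raise ValueError("inside mask shape does not match grid")
    if eval_mask is None:
        eval_mask = _evaluation_mask(grid, mesh, margin_voxels)
    else:
        eval_mask = np.asarray(eval_mask, dtype=bool).copy()
    eval_mask |= inside
    idx = np.argwhere(eval_mask)
    pts = grid.voxel_to_world(idx)
    md = _MeshDistance(mesh)
    dist, closest, tri = md.query(pts)

    sign = np.where(inside[tuple(idx.T)], 1.0, -1.0)
    half_diag = 0.5 * float(np.linalg.norm(grid.voxel_size))
    near = dist < half_diag
    if near.any():
        n_tri = mesh.face_normals[tri[near]]
        outward_side = np.einsum("ij,ij->i", pts[near] - closest[near], n_tri) > 0
        sign[near] = np.where(outward_side, -1.0, 1.0)

    if check_consistency:
        well_inside_claim = inside[tuple(idx.T)] & ~near
        if well_inside_claim.any():
            n_tri = mesh.face_normals[tri[well_inside_claim]]
            outside = (
                np.einsum(
                    "ij,ij->i", pts[well_inside_claim] - closest[well_inside_claim], n_tri
                )
                > 0
            )
            frac = outside.mean()
            if frac > 0.01:
                raise ValueError(
                    f"{frac:.1%} of 'inside' voxels lie outside the mesh; "
                    "mesh/mask mismatch"
                )

    data = np.full(grid.shape, np.nan)
    data[tuple(idx.T)] = sign * dist
    return SignedDistanceField(
        volume=ScalarVolume(data=data, affine=grid.affine.copy(), units="mm"),
        reference=reference,
    )


def normalized_depth(
    d1: SignedDistanceField, d2: SignedDistanceField
) -> NormalizedDepthField:
    """Solve (1 - w) d1 + w d2 = 0 voxelwise: w = d1 / (d1 - d2).

    Voxels where the denominator vanishes (|d1 - d2| < 1e-6 mm) or where
    either field is undefined are masked invalid.
    """
    if d1.data.shape != d2.data.shape or not np.allclose(d1.affine, d2.affine):
        raise ValueError("d1 and d2 are not on the same grid")
    den = d1.data - d2.data
    valid = np.isfinite(d1.data) & np.isfinite(d2.data) & (np.abs(den) > SINGULARITY_TOL)
    w = np.full(d1.data.shape, np.nan)
    w[valid] = d1.data[valid] / den[valid]
    return NormalizedDepthField(
        volume=ScalarVolume(data=w, affine=d1.affine.copy(), units="dimensionless"),
        valid=valid,
    )


def extract_w_isosurface(w: NormalizedDepthField, value: float) -> trimesh.Trimesh:
    """Mesh the ``w = value`` level set (world mm).

    Invalid voxels are filled below the iso level so they cannot generate
    spurious sheets; if disconnected fragments remain, the largest-area
    component is returned.
    """
    if not (0.0 <= value <= 1.0):
        raise ValueError("value must be within [0, 1]")
    field = np.where(w.valid, w.data, value - 10.0)
    field = np.nan_to_num(field, nan=value - 10.0)
    if not ((field.min() < value) and (field.max() > value)):
        raise ValueError(f"level set w={value} is empty")
    verts, faces, _, _ = measure.marching_cubes(field, level=value)
    verts = verts @ w.affine[:3, :3].T + w.affine[:3, 3]
    mesh = trimesh.Trimesh(vertices=verts, faces=faces, process=True)
    parts = mesh.split(only_watertight=False)
    if len(parts) > 1:
        mesh = max(parts, key=lambda m: m.area)
    if mesh.is_watertight and mesh.volume < 0:
        mesh.invert()
    return mesh
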