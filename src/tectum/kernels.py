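"""Depth-averaging kernels and binned depth profiles.

A depth kernel associates a vertex of the superficial surface S1 with a
set of deeper voxels.  Streamline kernels pool the voxelized trajectories
of all streamlines whose origins lie within a manifold (geodesic) radius of
the vertex, so the kernel follows the tissue; cylinder kernels extrude the
same manifold disk along its mean normal, the straight-line scheme used for
comparison.  Profiles average any scalar volume over kernel voxels in
sliding depth bins and are bootstrapped across runs for confidence
intervals.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import trimesh
from scipy.sparse.csgraph import dijkstra

from tectum.streamline import Streamline
from tectum.surface_model import edge_graph, outward_vertex_normals
from tectum.volume_io import ScalarVolume, Volume

KERNEL_KINDS = ("streamline", "cylinder")
#: depth metrics a kernel can carry per voxel
DEPTH_METRICS = ("euclidean_d1", "levelset_path", "normalized_w", "euclidean_d2")


@dataclass
class DepthKernel:
    """Voxels associated with one S1 vertex, with per-voxel depth values."""

    origin_vertex: int
    member_voxels: np.ndarray  # (k, 3) int voxel indices
    depths: dict = field(default_factory=dict)  # metric -> (k,) values
    kind: str = "streamline"

    @property
    def empty(self) -> bool:
        return len(self.member_voxels) == 0


@dataclass
class DepthProfile:
    """Binned mean curve of a scalar versus depth."""

    bin_centers: np.ndarray
    mean: np.ndarray
    ci_lo: np.ndarray
    ci_hi: np.ndarray
    n: np.ndarray
    metric: str = "levelset_path"

    def peak_depth(self) -> float:
        """Bin center of the maximum mean value (populated bins only)."""
        m = np.where(self.n > 0, self.mean, -np.inf)
        return float(self.bin_centers[int(np.argmax(m))])

    def to_dataframe(self):
        """Profile as a table (bin_center, mean, ci_lo, ci_hi, n)."""
        import pandas as pd

        return pd.DataFrame(
            {
                "bin_center": self.bin_centers,
                "mean": self.mean,
                "ci_lo": self.ci_lo,
                "ci_hi": self.ci_hi,
                "n": self.n,
            }
        )


def _voxelize_points(points: np.ndarray, grid: Volume) -> np.ndarray:
    inv = np.linalg.inv(grid.affine)
    ijk = np.rint(points @ inv[:3, :3].T + inv[:3, 3]).astype(int)
    ok = np.all((ijk >= 0) & (ijk < np.array(grid.shape)), axis=1)
    return np.unique(ijk[ok], axis=0)


def _geodesic_members(
    s1: trimesh.Trimesh, vertices: np.ndarray, radius: float
) -> list[np.ndarray]:
    """Vertex ids within geodesic ``radius`` of each requested vertex."""
    graph = edge_graph(s1)
    members = []
    chunk = 512
    for s in range(0, len(vertices), chunk):
        idx = vertices[s : s + chunk]
        dist = dijkstra(graph, indices=idx, limit=radius)
        for row in dist:
            members.append(np.nonzero(np.isfinite(row))[0])
    return members


def build_kernels(
    s1: trimesh.Trimesh,
    grid: Volume,
    streamlines: list[Streamline] | None = None,
    radius: float = 0.7,
    kind: str = "streamline",
    vertices: np.ndarray | None = None,
    depth_volumes: dict[str, ScalarVolume] | None = None,
    cylinder_span: tuple[float, float] = (-1.0, 4.0),
) -> list[DepthKernel]:
    """Build one depth-averaging kernel per requested S1 vertex.

    Parameters
    ----------
    s1 : superficial surface
    grid : volume defining the voxel grid the kernels live on
    streamlines : required for ``kind="streamline"``; only complete
        streamlines contribute, and a vertex with no complete streamline
        within ``radius`` yields an empty (flagged) kernel.
    radius : manifold gathering radius in mm (default 0.7)
    depth_volumes : optional ``{metric: volume}`` map sampled at the member
        voxels and stored on each kernel
    cylinder_span : depth range (mm along the mean normal, inward positive)
        over which cylinder kernels are extruded
    """
    if kind not in KERNEL_KINDS:
        raise ValueError(f"kind must be one of {KERNEL_KINDS}")
    if radius <= 0:
        raise ValueError("radius must be > 0")
    if vertices is None:
        vertices = np.arange(len(s1.vertices))
    vertices = np.asarray(vertices, dtype=int)
    members = _geodesic_members(s1, vertices, radius)

    kernels: list[DepthKernel] = []
    if kind == "streamline":
        if streamlines is None:
            raise ValueError("streamline kernels require streamlines")
        by_vertex: dict[int, Streamline] = {
            s.origin_vertex: s for s in streamlines if s.complete
        }
        for v, mem in zip(vertices, members):
            pts = [by_vertex[m].points for m in mem if m in by_vertex]
            vox = (
                _voxelize_points(np.vstack(pts), grid)
                if pts
                else np.empty((0, 3), dtype=int)
            )
            kernels.append(DepthKernel(int(v), vox, kind=kind))
    else:
        normals = outward_vertex_normals(s1)
        step = 0.5 * min(np.asarray(grid.voxel_size))
        t = np.arange(cylinder_span[0], cylinder_span[1] + step, step)
        for v, mem in zip(vertices, members):
            disk = s1.vertices[mem]
            n_mean = normals[mem].mean(axis=0)
            n_mean /= np.linalg.norm(n_mean)
            pts = (disk[:, None, :] - t[None, :, None] * n_mean).reshape(-1, 3)
            kernels.append(DepthKernel(int(v), _voxelize_points(pts, grid), kind=kind))

    if depth_volumes:
        for k in kernels:
            for metric, vol in depth_volumes.items():
                k.depths[metric] = (
                    vol.data[tuple(k.member_voxels.T)]
                    if not k.empty
                    else np.empty(0)
                )
    return kernels


def depth_profile(
    kernels: list[DepthKernel],
    scalar: ScalarVolume,
    metric: str = "levelset_path",
    span: tuple[float, float] = (-0.5, 3.5),
    step: float = 0.1,
    bin_width: float = 1.2,
) -> DepthProfile:
    """Sliding-bin mean of a scalar volume versus kernel depth.

    Bin centers run over ``span`` at ``step`` increments; each bin averages
    scalar values at kernel voxels whose depth lies within ``bin_width`` of
    the center (overlapping bins).  Empty bins are masked with n = 0.
    """
    vox_list, depth_list = [], []
    for k in kernels:
        if k.empty:
            continue
        if metric not in k.depths:
            raise ValueError(f"kernel lacks depth metric {metric!r}")
        vox_list.append(k.member_voxels)
        depth_list.append(k.depths[metric])
    if not vox_list:
        raise ValueError("all kernels are empty")
    vox = np.vstack(vox_list)
    depths = np.concatenate(depth_list)
    values = scalar.data[tuple(vox.T)]
    good = np.isfinite(depths) & np.isfinite(values)
    depths, values = depths[good], values[good]

    centers = np.arange(span[0], span[1] + step / 2, step)
    mean = np.full(len(centers), np.nan)
    ci_lo = np.full(len(centers), np.nan)
    ci_hi = np.full(len(centers), np.nan)
    n = np.zeros(len(centers), dtype=int)
    half = bin_width / 2.0
    order = np.argsort(depths)
    ds, vs = depths[order], values[order]
    for i, c in enumerate(centers):
        lo, hi = np.searchsorted(ds, [c - half, c + half])
        if hi > lo:
            seg = vs[lo:hi]
            mean[i] = seg.mean()
            n[i] = hi - lo
            sem = seg.std(ddof=1) / np.sqrt(n[i]) if n[i] > 1 else 0.0
            ci_lo[i] = mean[i] - sem
            ci_hi[i] = mean[i] + sem
    return DepthProfile(centers, mean, ci_lo, ci_hi, n, metric=metric)


def bootstrap_profile(
    run_profiles: list[DepthProfile],
    n_boot: int = 2000,
    seed: int | None = None,
) -> tuple[DepthProfile, np.ndarray]:
    """Bootstrap the across-run mean profile (resampling runs, 2000 draws).

    Returns the mean profile with percentile 68% confidence intervals and
    the per-iteration peak-depth distribution.
    """
    if len(run_profiles) < 2:
        raise ValueError("bootstrap requires at least 2 runs")
    centers = run_profiles[0].bin_centers
    for p in run_profiles[1:]:
        if not np.allclose(p.bin_centers, centers):
            raise ValueError("run profiles have mismatched bins")
    stack = np.vstack([p.mean for p in run_profiles])  # (runs, bins)
    rng = np.random.default_rng(seed)
    n_runs = len(run_profiles)
    idx = rng.integers(0, n_runs, size=(n_boot, n_runs))
    boot_means = np.nanmean(stack[idx], axis=1)  # (n_boot, bins)
    populated = np.isfinite(stack).all(axis=0)
    masked = np.where(populated[None, :], boot_means, -np.inf)
    peaks = centers[np.argmax(masked, axis=1)]
    mean = np.nanmean(boot_means, axis=0)
    ci_lo = np.nanpercentile(boot_means, 16, axis=0)
    ci_hi = np.nanpercentile(boot_means, 84, axis=0)
    n = np.where(populated, n_runs, 0)
    prof = DepthProfile(
        centers, mean, ci_lo, ci_hi, n, metric=run_profiles[0].metric
    )
    return prof, peaks
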