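"""Localization of the periaqueductal gray (PAG) outer boundary.

The PAG forms a roughly elliptical annulus of gray matter around the
cerebral aqueduct (CA).  Its outer boundary is estimated from gray-matter
tissue-probability maps: probability is profiled against Euclidean distance
from CA (d2), the across-subject spatial uncertainty U of an
iso-probability boundary is minimized to pick the working threshold P_thr,
and the thresholded contour in planes normal to the skeletonized CA axis is
fit with ellipses whose stack reconstructs a smooth 3D boundary surface
(S_ellipse) comparable against the iso-probability surface (S_PAG).

The spatial uncertainty converts probability variability into positional
variability of the boundary:

    U = (sigma_P / P) * |dP/dd2|^(-1)    [mm]

where sigma_P is the across-subject SD of P at each distance from CA.  For
a family of boundaries that share their shape but whose positions jitter
with SD sigma_c, the delta method gives U ~ sigma_c / P, so U falls with P
and the optimum sits at the largest usable probability.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import trimesh
from scipy import ndimage
from scipy.ndimage import map_coordinates
from scipy.optimize import least_squares
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import dijkstra
from skimage import measure
from skimage.morphology import skeletonize

from tectum.depth_field import SignedDistanceField, _MeshDistance
from tectum.kernels import DepthKernel
from tectum.volume_io import (
    LABEL_AQUEDUCT,
    LabelVolume,
    ScalarVolume,
    upsample_labels,
)


@dataclass
class ProbabilityDepthProfile:
    """Gray-matter probability binned against distance from CA.

    ``distance_mm`` is the unsigned Euclidean distance from the aqueduct
    surface (-d2 inside the brainstem), binned at 0.05 mm increments.
    """

    distance_mm: np.ndarray
    per_subject: np.ndarray  # (n_subjects, n_bins), NaN where empty
    mean: np.ndarray
    sd: np.ndarray
    n_subjects_per_bin: np.ndarray


@dataclass
class UncertaintyCurve:
    """Spatial uncertainty of the boundary location versus probability."""

    P: np.ndarray
    U: np.ndarray  # mm
    n_subjects_per_bin: np.ndarray
    distance_mm: np.ndarray
    P_thr: float | None = None


@dataclass
class AxisCurve:
    """Ordered CA centerline with tangents and normalized arclength."""

    points: np.ndarray  # (m, 3) world mm
    tangents: np.ndarray  # (m, 3) unit
    arclength: np.ndarray  # (m,) mm from the first point

    @property
    def normalized_arclength(self) -> np.ndarray:
        total = self.arclength[-1]
        return self.arclength / total if total > 0 else self.arclength


@dataclass
class EllipseFit:
    """Per-slice PAG boundary ellipse, centered on the CA axis."""

    axis_index: int
    arclength: float
    center: np.ndarray  # world mm, on the CA axis
    a: float  # left-right semi-axis, mm
    b: float  # dorsal-ventral semi-axis, mm
    rotation: float  # radians, in-plane
    rms: float  # mm radial residual
    n_points: int
    u_axis: np.ndarray = field(repr=False, default=None)  # in-plane LR unit
    v_axis: np.ndarray = field(repr=False, default=None)  # in-plane DV unit

    @property
    def epsilon(self) -> float:
        return self.b / self.a


def probability_depth_profile(
    kernels: list[DepthKernel],
    prob_volumes: list[ScalarVolume] | ScalarVolume,
    d2: SignedDistanceField,
    increment: float = 0.05,
    max_distance: float | None = None,
) -> ProbabilityDepthProfile:
    """Mean gray-matter probability per 0.05 mm bin of distance from CA.

    One probability volume per subject; kernels define the pooled voxel
    set (the same anatomy-driven kernels for all subjects of a phantom
    family).
    """
    if isinstance(prob_volumes, ScalarVolume):
        prob_volumes = [prob_volumes]
    # deduplicate kernel members in chunks to bound memory for large sets
    vox = np.empty((0, 3), dtype=int)
    block: list[np.ndarray] = []
    size = 0
    for k in kernels:
        if k.empty:
            continue
        block.append(k.member_voxels)
        size += len(k.member_voxels)
        if size > 2_000_000:
            vox = np.unique(np.vstack([vox, *block]), axis=0)
            block, size = [], 0
    if block:
        vox = np.unique(np.vstack([vox, *block]), axis=0)
    dist = -d2.data[tuple(vox.T)]  # distance from CA, positive in BS
    good = np.isfinite(dist) & (dist >= 0)
    vox, dist = vox[good], dist[good]
    if max_distance is None:
        max_distance = float(dist.max())
    edges = np.arange(0.0, max_distance + increment, increment)
    centers = 0.5 * (edges[:-1] + edges[1:])
    which = np.digitize(dist, edges) - 1
    ok = (which >= 0) & (which < len(centers))

    per_subject = np.full((len(prob_volumes), len(centers)), np.nan)
    for si, pv in enumerate(prob_volumes):
        vals = pv.data[tuple(vox.T)]
        good_v = ok & np.isfinite(vals)
        sums = np.bincount(which[good_v], weights=vals[good_v], minlength=len(centers))
        cnts = np.bincount(which[good_v], minlength=len(centers))
        with np.errstate(invalid="ignore"):
            per_subject[si] = np.where(cnts > 0, sums / np.maximum(cnts, 1), np.nan)
    n_per_bin = np.isfinite(per_subject).sum(axis=0)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        mean = np.nanmean(per_subject, axis=0)
        sd = np.nanstd(per_subject, axis=0, ddof=1)
    return ProbabilityDepthProfile(centers, per_subject, mean, sd, n_per_bin)


def _moving_average(x: np.ndarray, width: int) -> np.ndarray:
    """NaN-aware centered moving average (edge-padded)."""
    kernel = np.ones(width)
    pad = width // 2
    xp = np.pad(np.asarray(x, dtype=float), pad, mode="edge")
    good = np.isfinite(xp)
    num = np.convolve(np.where(good, xp, 0.0), kernel, mode="valid")
    den = np.convolve(good.astype(float), kernel, mode="valid")
    with np.errstate(invalid="ignore", divide="ignore"):
        out = np.where(den > 0, num / den, np.nan)
    return out


def _five_point_derivative(y: np.ndarray, h: float) -> np.ndarray:
    d = np.full(len(y), np.nan)
    if len(y) >= 5:
        d[2:-2] = (-y[4:] + 8 * y[3:-1] - 8 * y[1:-3] + y[:-4]) / (12 * h)
    return d


def spatial_uncertainty(
    profile: ProbabilityDepthProfile,
    mode: str = "dimensional",
    derivative_tol: float = 1e-4,
    smooth_bins: int = 9,
) -> UncertaintyCurve:
    """Across-subject spatial uncertainty U of the probability boundary.

    ``mode="dimensional"`` computes U = (sigma_P / P) / |dP/dd2| in mm (the
    default; U must carry length units to be a positional uncertainty);
    ``mode="product"`` computes the alternative reading
    U = (sigma_P / P) * |dP/dd2|.

    Each subject's binned profile is moving-average smoothed (default 9
    bins = 0.45 mm at the 0.05 mm binning) before the across-subject mean,
    SD and five-point-stencil derivative are taken, so numerator and
    denominator refer to the same smeared profile and voxelization jitter
    in the 0.05-mm bins does not leak into the ratio.
    """
    if profile.per_subject.shape[0] < 2:
        raise ValueError("spatial uncertainty requires >= 2 subjects")
    if mode not in ("dimensional", "product"):
        raise ValueError("mode must be 'dimensional' or 'product'")
    h = float(np.diff(profile.distance_mm).mean())
    smoothed = np.vstack(
        [_moving_average(row, smooth_bins) for row in profile.per_subject]
    )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        mean = np.nanmean(smoothed, axis=0)
        sd = np.nanstd(smoothed, axis=0, ddof=1)
    dP = _five_point_derivative(mean, h)
    with np.errstate(divide="ignore", invalid="ignore"):
        rel = sd / mean
        U = rel / np.abs(dP) if mode == "dimensional" else rel * np.abs(dP)
    U[np.abs(dP) < derivative_tol] = np.nan
    U[~np.isfinite(U)] = np.nan
    return UncertaintyCurve(
        P=mean,
        U=U,
        n_subjects_per_bin=profile.n_subjects_per_bin,
        distance_mm=profile.distance_mm,
    )


def bin_uncertainty_by_probability(
    curve: UncertaintyCurve, p_bin_width: float = 0.02
) -> UncertaintyCurve:
    """Re-express U as a function of gray-matter probability.

    Depth bins are grouped by their mean probability into bins of width
    ``p_bin_width`` and U is averaged within each, which averages out the
    voxelization jitter of the fine depth bins.  The returned curve's
    ``distance_mm`` holds the mean depth of each P bin.
    """
    good = np.isfinite(curve.U) & np.isfinite(curve.P)
    edges = np.arange(0.0, 1.0 + p_bin_width, p_bin_width)
    centers = 0.5 * (edges[:-1] + edges[1:])
    which = np.digitize(curve.P[good], edges) - 1
    which = np.clip(which, 0, len(centers) - 1)
    U = np.full(len(centers), np.nan)
    dmm = np.full(len(centers), np.nan)
    nsub = np.zeros(len(centers), dtype=int)
    for b in np.unique(which):
        sel = which == b
        U[b] = curve.U[good][sel].mean()
        dmm[b] = curve.distance_mm[good][sel].mean()
        nsub[b] = int(curve.n_subjects_per_bin[good][sel].max())
    keep = np.isfinite(U)
    return UncertaintyCurve(
        P=centers[keep],
        U=U[keep],
        n_subjects_per_bin=nsub[keep],
        distance_mm=dmm[keep],
    )


def optimize_threshold(curve: UncertaintyCurve) -> float:
    """Probability threshold minimizing the mean spatial uncertainty.

    Restricted to bins where at least half the subjects contribute; ties
    are broken toward the larger probability.
    """
    n_max = curve.n_subjects_per_bin.max()
    usable = (
        np.isfinite(curve.U)
        & np.isfinite(curve.P)
        & (curve.n_subjects_per_bin >= n_max / 2)
        & (curve.P > 0)
        & (curve.P < 1)
    )
    if usable.sum() < 5:
        raise ValueError("spatial uncertainty defined on fewer than 5 P values")
    P, U = curve.P[usable], curve.U[usable]
    best = np.nonzero(U <= U.min() + 1e-12)[0]
    p_thr = float(P[best].max())
    curve.P_thr = p_thr
    return p_thr


def _skeleton_longest_path(mask: np.ndarray) -> np.ndarray:
    """Ordered voxel indices of the longest geodesic path of a 3D skeleton."""
    pts = np.argwhere(mask)
    tree_idx = {tuple(p): i for i, p in enumerate(pts)}
    offsets = np.array(
        [(i, j, k) for i in (-1, 0, 1) for j in (-1, 0, 1) for k in (-1, 0, 1)
         if (i, j, k) != (0, 0, 0)]
    )
    rows, cols, w = [], [], []
    for oi, off in enumerate(offsets):
        nb = pts + off
        for i, p in enumerate(nb):
            j = tree_idx.get(tuple(p))
            if j is not None:
                rows.append(i)
                cols.append(j)
                w.append(float(np.linalg.norm(off)))
    g = csr_matrix((w, (rows, cols)), shape=(len(pts), len(pts)))
    # double sweep: farthest from an arbitrary node, then farthest from that
    d0 = dijkstra(g, indices=0, min_only=True)
    a = int(np.argmax(np.where(np.isfinite(d0), d0, -1)))
    d1, pred = dijkstra(g, indices=a, return_predecessors=True)
    b = int(np.argmax(np.where(np.isfinite(d1), d1, -1)))
    path = [b]
    while path[-1] != a and pred[path[-1]] >= 0:
        path.append(int(pred[path[-1]]))
    return pts[path[::-1]]


def ca_axis(
    ca: LabelVolume,
    upsample_factor: int = 2,
    smooth_window: int = 5,
) -> AxisCurve:
    """Skeletonize the aqueduct segmentation into an ordered centerline.

    The CA label is upsampled (x2 by default), thinned to a 3D skeleton,
    reduced to its longest path, converted to world mm and smoothed with a
    short moving average before tangents are taken by central differences.
    """
    mask = ca.mask(LABEL_AQUEDUCT)
    if not mask.any():
        raise ValueError("no aqueduct voxels to skeletonize")
    _, ncomp = ndimage.label(mask, structure=np.ones((3, 3, 3), int))
    if ncomp != 1:
        raise ValueError(f"aqueduct has {ncomp} connected components, expected 1")
    from itertools import permutations

    up = upsample_labels(ca, upsample_factor)
    up_mask = up.mask(LABEL_AQUEDUCT)
    # the 3D thinning is sensitive to axis order and can fully erode a
    # symmetric tube for some orientations; take the richest skeleton
    # over all axis permutations (deterministic tie-break by order)
    skel = None
    best = -1
    for order in permutations(range(3)):
        skel_t = skeletonize(np.ascontiguousarray(up_mask.transpose(order)))
        n = int(skel_t.sum())
        if n > best:
            best = n
            cand = np.zeros_like(up_mask)
            if n:
                cand[tuple(np.argwhere(skel_t)[:, np.argsort(order)].T)] = True
            skel = cand
    if skel is None or not skel.any():
        raise ValueError("skeletonization produced no voxels")
    path_vox = _skeleton_longest_path(skel)
    pts = up.voxel_to_world(path_vox)
    if len(pts) >= smooth_window:
        pts = np.column_stack(
            [_moving_average(pts[:, k], smooth_window) for k in range(3)]
        )
    seg = np.linalg.norm(np.diff(pts, axis=0), axis=1)
    arc = np.concatenate([[0.0], np.cumsum(seg)])
    tangents = np.gradient(pts, arc, axis=0)
    tangents /= np.linalg.norm(tangents, axis=1, keepdims=True)
    return AxisCurve(points=pts, tangents=tangents, arclength=arc)


def _in_plane_axes(
    tangent: np.ndarray,
    lr_direction: np.ndarray,
    dv_direction: np.ndarray,
) -> tuple[np.ndarray, np.ndarray]:
    """Project the world left-right / dorsal-ventral axes into the slice."""
    t = tangent / np.linalg.norm(tangent)
    u = lr_direction - (lr_direction @ t) * t
    u /= np.linalg.norm(u)
    v = dv_direction - (dv_direction @ t) * t - (dv_direction @ u) * u
    v /= np.linalg.norm(v)
    return u, v


def _point_in_polygon(poly: np.ndarray, x: float = 0.0, y: float = 0.0) -> bool:
    """Ray-crossing test; ``poly`` is (n, 2), closed or open."""
    px, py = poly[:, 0], poly[:, 1]
    inside = False
    j = len(poly) - 1
    for i in range(len(poly)):
        if (py[i] > y) != (py[j] > y):
            xint = (px[j] - px[i]) * (y - py[i]) / (py[j] - py[i]) + px[i]
            if x < xint:
                inside = not inside
        j = i
    return inside


def _fit_centered_ellipse(xy: np.ndarray) -> tuple[float, float, float, float]:
    """LSQ ellipse through points, center fixed at origin.

    Minimizes the radial residual r_i - r_ell(theta_i; a, b, phi).
    Returns (a, b, phi, rms).
    """
    r = np.linalg.norm(xy, axis=1)
    theta = np.arctan2(xy[:, 1], xy[:, 0])

    def radius(params, th):
        a, b, phi = params
        c, s = np.cos(th - phi), np.sin(th - phi)
        return (a * b) / np.sqrt((b * c) ** 2 + (a * s) ** 2)

    a0 = max(np.abs(xy[:, 0]).max(), 1e-3)
    b0 = max(np.abs(xy[:, 1]).max(), 1e-3)
    res = least_squares(
        lambda p: radius(p, theta) - r,
        x0=[a0, b0, 0.0],
        bounds=([1e-3, 1e-3, -np.pi / 2], [np.inf, np.inf, np.pi / 2]),
    )
    a, b, phi = res.x
    rms = float(np.sqrt(np.mean((radius(res.x, theta) - r) ** 2)))
    return float(a), float(b), float(phi), rms


def fit_ellipse_stack(
    prob: ScalarVolume,
    axis: AxisCurve,
    p_thr: float,
    lr_direction: np.ndarray = (1.0, 0.0, 0.0),
    dv_direction: np.ndarray = (0.0, 1.0, 0.0),
    slice_extent: float = 8.0,
    slice_step: float = 0.2,
) -> list[EllipseFit]:
    """Fit a PAG boundary ellipse in each plane normal to the CA axis.

    At every axis point the probability volume is resampled on a regular
    2D grid in the normal plane, the iso-contour at ``p_thr`` is extracted
    by marching squares, the outermost closed contour enclosing the axis is
    kept, and an origin-centered ellipse (semi-axes along the projected
    left-right and dorsal-ventral directions plus a fitted rotation) is
    estimated by least squares on the radial residual.  Slices without a
    closed enclosing contour are skipped.
    """
    if not (0.0 < p_thr < 1.0):
        raise ValueError("p_thr must be in (0, 1)")
    lr = np.asarray(lr_direction, dtype=float)
    dv = np.asarray(dv_direction, dtype=float)
    inv = np.linalg.inv(prob.affine)
    coords = np.arange(-slice_extent, slice_extent + slice_step / 2, slice_step)
    X, Y = np.meshgrid(coords, coords, indexing="ij")
    fits: list[EllipseFit] = []
    for i, (c, t) in enumerate(zip(axis.points, axis.tangents)):
        u, v = _in_plane_axes(t, lr, dv)
        world = c + X[..., None] * u + Y[..., None] * v
        vox = world @ inv[:3, :3].T + inv[:3, 3]
        plane = map_coordinates(
            prob.data, vox.reshape(-1, 3).T, order=1, mode="constant", cval=0.0
        ).reshape(X.shape)
        contours = measure.find_contours(plane, level=p_thr)
        best = None
        best_extent = -np.inf
        for cont in contours:
            if np.linalg.norm(cont[0] - cont[-1]) > 1.0:
                continue  # open contour
            xy = np.column_stack(
                [np.interp(cont[:, 0], np.arange(len(coords)), coords),
                 np.interp(cont[:, 1], np.arange(len(coords)), coords)]
            )
            if not _point_in_polygon(xy):
                continue
            extent = np.abs(xy).max()
            if extent > best_extent:
                best, best_extent = xy, extent
        if best is None or len(best) < 8:
            continue
        a, b, phi, rms = _fit_centered_ellipse(best)
        fits.append(
            EllipseFit(
                axis_index=i,
                arclength=float(axis.arclength[i]),
                center=c.copy(),
                a=a,
                b=b,
                rotation=phi,
                rms=rms,
                n_points=len(best),
                u_axis=u,
                v_axis=v,
            )
        )
    return fits


def ellipse_table(fits: list[EllipseFit]):
    """Fitted ellipse parameters along the axis as a table."""
    import pandas as pd

    return pd.DataFrame(
        {
            "arclength_mm": [f.arclength for f in fits],
            "a_mm": [f.a for f in fits],
            "b_mm": [f.b for f in fits],
            "epsilon": [f.epsilon for f in fits],
            "rotation_rad": [f.rotation for f in fits],
            "rms_mm": [f.rms for f in fits],
            "n_points": [f.n_points for f in fits],
        }
    )


def rasterize_ellipses(
    fits: list[EllipseFit],
    axis: AxisCurve,
    grid: ScalarVolume | LabelVolume,
    sample_step: float | None = None,
) -> np.ndarray:
    """Flood-fill the fitted ellipses back into a voxel mask on ``grid``.

    Each ellipse is sampled densely in its slice plane (plus small offsets
    along the tangent covering the inter-slice spacing) and the covered
    voxels are unioned.
    """
    if len(fits) < 3:
        raise ValueError("need at least 3 valid ellipse fits to reconstruct")
    mask = np.zeros(grid.shape, dtype=bool)
    inv = np.linalg.inv(grid.affine)
    vox_min = float(np.min(np.asarray(grid.voxel_size)))
    if sample_step is None:
        sample_step = 0.4 * vox_min
    arcs = [f.arclength for f in fits]
    spacing = np.median(np.diff(arcs)) if len(arcs) > 1 else vox_min
    t_offsets = np.linspace(-spacing / 2, spacing / 2, max(int(spacing / sample_step) + 1, 1))
    for f in fits:
        t = axis.tangents[f.axis_index]
        ext = max(f.a, f.b)
        c1 = np.arange(-ext, ext + sample_step / 2, sample_step)
        Xg, Yg = np.meshgrid(c1, c1, indexing="ij")
        cphi, sphi = np.cos(f.rotation), np.sin(f.rotation)
        xr = Xg * cphi + Yg * sphi
        yr = -Xg * sphi + Yg * cphi
        inside = (xr / f.a) ** 2 + (yr / f.b) ** 2 <= 1.0
        pts2 = np.column_stack([Xg[inside], Yg[inside]])
        for dt in t_offsets:
            world = (
                f.center
                + dt * t
                + pts2[:, 0, None] * f.u_axis
                + pts2[:, 1, None] * f.v_axis
            )
            ijk = np.rint(world @ inv[:3, :3].T + inv[:3, 3]).astype(int)
            ok = np.all((ijk >= 0) & (ijk < np.array(grid.shape)), axis=1)
            mask[tuple(ijk[ok].T)] = True
    return mask


def surface_separation(
    mesh_a: trimesh.Trimesh, mesh_b: trimesh.Trimesh
) -> dict[str, float]:
    """Symmetric per-vertex nearest-surface separation statistics (mm)."""
    da, _, _ = _MeshDistance(mesh_b).query(mesh_a.vertices)
    db, _, _ = _MeshDistance(mesh_a).query(mesh_b.vertices)
    sep = np.concatenate([da, db])
    return {
        "mean": float(sep.mean()),
        "max": float(sep.max()),
        "fraction_gt_2mm": float((sep > 2.0).mean()),
    }


def reconstruct_and_compare(
    fits: list[EllipseFit],
    axis: AxisCurve,
    grid: ScalarVolume | LabelVolume,
    s_pag: trimesh.Trimesh | None = None,
    refine_iterations: int = 5,
) -> tuple[trimesh.Trimesh, dict[str, float] | None]:
    """Composite the ellipse stack into S_ellipse and compare with S_PAG.

    The filled ellipse slices are unioned into a 3D segmentation, surfaced
    and refined; if an iso-probability surface ``s_pag`` is supplied, the
    symmetric vertex separation statistics (mean, max, fraction above 2 mm)
    are returned alongside.
    """
    from tectum.surface_model import extract_isosurface, refine_surface

    mask = rasterize_ellipses(fits, axis, grid)
    padded = np.pad(mask, 2)
    affine = grid.affine.copy()
    affine[:3, 3] -= affine[:3, :3] @ np.array([2.0, 2.0, 2.0])
    vol = ScalarVolume(data=padded.astype(float), affine=affine)
    mesh = extract_isosurface(vol, 0.5)
    mesh = refine_surface(mesh, refine_iterations)
    mesh.metadata["role"] = "S_ellipse"
    stats = surface_separation(s_pag, mesh) if s_pag is not None else None
    return mesh, stats
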