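"""Collicular landmarks and tissue thickness under three depth metrics.

Thickness is measured from the superficial surface S1 to the PAG boundary
surface: along the inward surface normal (Euclidean), along the level-set
streamline originating at the vertex (streamline path), and as the
normalized depth w interpolated where that streamline crosses the PAG.
Landmarks -- the four collicular peaks and the two intercollicular sulci --
are located automatically from surface curvature and base-plane fits, and
reported thickness values are smoothed with a Gaussian manifold-distance
kernel (2 mm diameter, 1 mm FWHM).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import trimesh
from scipy.ndimage import map_coordinates
from scipy.spatial import cKDTree

from tectum.depth_field import NormalizedDepthField, _MeshDistance
from tectum.streamline import Streamline
from tectum.surface_model import (
    edge_graph,
    geodesic_distances,
    mean_curvature,
    outward_vertex_normals,
)
from tectum.volume_io import LABEL_COLLICULUS, LabelVolume

METRICS = ("euclidean", "streamline", "normalized")

#: Gaussian smoothing kernel: 2 mm diameter, 1 mm full-width-at-half-maximum
SMOOTHING_RADIUS_MM = 1.0
SMOOTHING_FWHM_MM = 1.0
LANDMARK_NAMES = ("SC-L", "SC-R", "SC-ICS", "IC-L", "IC-R", "IC-ICS")


@dataclass
class Plane:
    point: np.ndarray
    normal: np.ndarray

    def signed_distance(self, pts: np.ndarray) -> np.ndarray:
        return (np.atleast_2d(pts) - self.point) @ self.normal


@dataclass
class LandmarkSet:
    """Six landmarks (vertex ids + world mm) and the partition planes."""

    vertices: dict[str, int]
    points: dict[str, np.ndarray]
    sagittal_plane: Plane
    axial_plane: Plane
    base_planes: dict[str, Plane]
    s1a_vertices: np.ndarray


def _best_fit_plane(pts: np.ndarray, weights: np.ndarray | None = None) -> Plane:
    """Total-least-squares plane; optional per-point weights.

    Mesh callers pass vertex areas as weights so the fit reflects the
    surface, not the rasterization-dependent vertex density.
    """
    if weights is None:
        weights = np.ones(len(pts))
    weights = weights / weights.sum()
    c = weights @ pts
    d = (pts - c) * np.sqrt(weights)[:, None]
    _, _, vt = np.linalg.svd(d, full_matrices=False)
    return Plane(point=c, normal=vt[-1])


def _vertex_areas(mesh: trimesh.Trimesh) -> np.ndarray:
    areas = np.zeros(len(mesh.vertices))
    fa = mesh.area_faces
    for k in range(3):
        np.add.at(areas, mesh.faces[:, k], fa / 3.0)
    return areas


def _line_plane_intersection(p0, p1, plane: Plane) -> np.ndarray:
    d = p1 - p0
    denom = d @ plane.normal
    if abs(denom) < 1e-12:
        raise ValueError("peak-to-peak line is parallel to the sagittal plane")
    t = ((plane.point - p0) @ plane.normal) / denom
    return p0 + t * d


def build_s1a_vertices(
    s1: trimesh.Trimesh,
    labels: LabelVolume,
    expand_mm: float = 2.0,
) -> np.ndarray:
    """S1 vertex ids of the collicular patch S_1A.

    Colliculus-labelled voxels are mapped to S1 by nearest-neighbor
    association and the resulting vertex set is expanded by an extra
    manifold distance (2 mm by default).
    """
    vox = np.argwhere(labels.mask(LABEL_COLLICULUS))
    if len(vox) == 0:
        raise ValueError("colliculus label (3) is empty")
    pts = labels.voxel_to_world(vox)
    tree = cKDTree(s1.vertices)
    _, seeds = tree.query(pts)
    seeds = np.unique(seeds)
    dist = geodesic_distances(s1, seeds, limit=expand_mm)
    return np.nonzero(np.isfinite(dist))[0]


def locate_landmarks(
    s1: trimesh.Trimesh,
    s2: trimesh.Trimesh,
    labels: LabelVolume,
    curvature_sign: float = 1.0,
    axial_direction: np.ndarray = (0.0, 0.0, 1.0),
    axial_bin_mm: float = 0.5,
    sagittal_tol_mm: float = 0.25,
    min_quadrant_vertices: int = 10,
    base_plane_mode: str = "positive",
) -> LandmarkSet:
    """Locate the four collicular peaks and both intercollicular sulci.

    The collicular patch S_1A (colliculus voxels mapped to S1, expanded by
    2 mm of manifold distance) is split into quadrants by a quasi-sagittal
    plane (best fit through the aqueduct surface vertices) and an axial
    plane (midpoint of the 0.5-mm axial bin with the most negative mean
    curvature, i.e. the transverse groove between SC and IC).  In each
    quadrant a base plane is fit through the positive-curvature vertices
    and the peak is the vertex farthest from it; each intercollicular
    sulcus is the S1 vertex nearest the intersection of the peak-to-peak
    line with the sagittal plane, required to lie within 0.25 mm of that
    plane.

    ``curvature_sign`` flips the curvature convention; the default makes
    convex hillocks positive and the concave grooves negative.
    ``base_plane_mode="zero"`` fits the base plane through the near-zero
    curvature band instead of the positive-curvature set.
    """
    s1a = build_s1a_vertices(s1, labels)
    curv = curvature_sign * mean_curvature(s1)
    verts = s1.vertices

    sagittal = _best_fit_plane(np.asarray(s2.vertices), _vertex_areas(s2))

    ax_dir = np.asarray(axial_direction, dtype=float)
    ax_dir = ax_dir / np.linalg.norm(ax_dir)
    ax_pos = verts[s1a] @ ax_dir
    bins = np.arange(ax_pos.min(), ax_pos.max() + axial_bin_mm, axial_bin_mm)
    which = np.digitize(ax_pos, bins) - 1
    bin_curv = np.full(len(bins), np.nan)
    for b in range(len(bins)):
        sel = which == b
        if sel.sum() >= 3:
            bin_curv[b] = curv[s1a[sel]].mean()
    groove_bin = int(np.nanargmin(bin_curv))
    axial_pos = bins[groove_bin] + axial_bin_mm / 2
    axial = Plane(point=axial_pos * ax_dir, normal=ax_dir)

    side_lr = sagittal.signed_distance(verts[s1a]).ravel()
    side_ax = axial.signed_distance(verts[s1a]).ravel()
    # orient: SC = axial side containing the larger superior coordinate span
    quadrants = {
        "SC-L": s1a[(side_lr < 0) & (side_ax > 0)],
        "SC-R": s1a[(side_lr >= 0) & (side_ax > 0)],
        "IC-L": s1a[(side_lr < 0) & (side_ax <= 0)],
        "IC-R": s1a[(side_lr >= 0) & (side_ax <= 0)],
    }

    vertices: dict[str, int] = {}
    points: dict[str, np.ndarray] = {}
    base_planes: dict[str, Plane] = {}
    for name, quad in quadrants.items():
        if len(quad) < min_quadrant_vertices:
            raise ValueError(
                f"quadrant {name} has only {len(quad)} vertices "
                f"(need >= {min_quadrant_vertices})"
            )
        qcurv = curv[quad]
        if base_plane_mode == "zero":
            band = np.abs(qcurv) < np.percentile(np.abs(qcurv), 10)
            base_set = quad[band] if band.sum() >= 3 else quad
        else:
            base_set = quad[qcurv > 0]
            if len(base_set) < 3:
                band = np.abs(qcurv) < np.percentile(np.abs(qcurv), 10)
                base_set = quad[band] if band.sum() >= 3 else quad
                warnings.warn(
                    f"{name}: no positive-curvature vertices; using the "
                    "near-zero curvature band for the base plane"
                )
        plane = _best_fit_plane(verts[base_set])
        # orient the base-plane normal outward so the peak search looks on
        # the convex side of the colliculus
        mean_n = outward_vertex_normals(s1)[quad].mean(axis=0)
        if plane.normal @ mean_n < 0:
            plane = Plane(point=plane.point, normal=-plane.normal)
        base_planes[name] = plane
        d = plane.signed_distance(verts[quad])
        peak = int(quad[int(np.argmax(d))])
        vertices[name] = peak
        points[name] = verts[peak].copy()

    for pair, ics in (("SC", "SC-ICS"), ("IC", "IC-ICS")):
        cross = _line_plane_intersection(
            points[f"{pair}-L"], points[f"{pair}-R"], sagittal
        )
        near_plane = np.abs(sagittal.signed_distance(verts[s1a]).ravel()) <= sagittal_tol_mm
        candidates = s1a[near_plane]
        if len(candidates) == 0:
            warnings.warn(
                f"{ics}: no vertex within {sagittal_tol_mm} mm of the "
                "sagittal plane; using the nearest vertex"
            )
            candidates = s1a
        d = np.linalg.norm(verts[candidates] - cross, axis=1)
        v = int(candidates[int(np.argmin(d))])
        vertices[ics] = v
        points[ics] = verts[v].copy()

    return LandmarkSet(
        vertices=vertices,
        points=points,
        sagittal_plane=sagittal,
        axial_plane=axial,
        base_planes=base_planes,
        s1a_vertices=s1a,
    )


def _ray_mesh_first_hit(
    origins: np.ndarray,
    directions: np.ndarray,
    mesh: trimesh.Trimesh,
    chunk_pairs: int = 4_000_000,
) -> np.ndarray:
    """First-hit distance per ray (Moller-Trumbore, vectorized); NaN = miss."""
    tri = np.asarray(mesh.triangles, dtype=float)
    v0, e1, e2 = tri[:, 0], tri[:, 1] - tri[:, 0], tri[:, 2] - tri[:, 0]
    n_rays, n_tris = len(origins), len(tri)
    best = np.full(n_rays, np.nan)
    rows = max(1, chunk_pairs // max(n_tris, 1))
    eps = 1e-12
    for s in range(0, n_rays, rows):
        O = origins[s : s + rows][:, None, :]
        D = directions[s : s + rows][:, None, :]
        h = np.cross(D, e2[None, :, :])
        det = np.einsum("rtk,tk->rt", h, e1)
        with np.errstate(divide="ignore", invalid="ignore"):
            inv_det = np.where(np.abs(det) > eps, 1.0 / det, np.nan)
            S = O - v0[None, :, :]
            u = np.einsum("rtk,rtk->rt", S, h) * inv_det
            q = np.cross(S, e1[None, :, :])
            v = np.einsum("rtk,rtk->rt", q, D)
            v = v * inv_det
            t = np.einsum("rtk,tk->rt", q, e2) * inv_det
        hit = (
            np.isfinite(t)
            & (u >= -1e-9)
            & (v >= -1e-9)
            & (u + v <= 1 + 1e-9)
            & (t > 1e-9)
        )
        t = np.where(hit, t, np.inf)
        tmin = t.min(axis=1)
        best[s : s + len(tmin)] = np.where(np.isfinite(tmin), tmin, np.nan)
    return best


def _signed_distance_to_mesh(
    points: np.ndarray, md: _MeshDistance, near_band: float = 2.0
) -> np.ndarray:
    """Signed distance, inside-positive, sign from nearest-triangle normal.

    Points farther than ``near_band`` mm from the surface (by a cheap
    triangle-centroid bound) get the centroid distance instead of the
    exact one -- crossing detection only needs exact values near the
    surface and correct signs elsewhere.
    """
    points = np.asarray(points, dtype=float)
    centroids = md.triangles.mean(axis=1)
    r_max = float(np.linalg.norm(md.triangles - centroids[:, None, :], axis=2).max())
    tree = cKDTree(centroids)
    dc, ti = tree.query(points)
    out = np.empty(len(points))
    far = dc > near_band + r_max
    if far.any():
        n = md.mesh.face_normals[ti[far]]
        outside = np.einsum("ij,ij->i", points[far] - centroids[ti[far]], n) > 0
        out[far] = np.where(outside, -dc[far], dc[far])
    near = ~far
    if near.any():
        dist, closest, tri = md.query(points[near])
        n = md.mesh.face_normals[tri]
        outside = np.einsum("ij,ij->i", points[near] - closest, n) > 0
        out[near] = np.where(outside, -dist, dist)
    return out


def _streamline_pag_crossing(
    s: Streamline, md: _MeshDistance
) -> tuple[float, np.ndarray] | None:
    """Path depth and point where the streamline first enters the PAG."""
    sd = _signed_distance_to_mesh(s.points, md)
    depth = s.depth_from_surface
    after = depth >= 0  # only the inward segment can reach the PAG
    crossings = np.nonzero((sd[:-1] < 0) & (sd[1:] >= 0) & after[1:])[0]
    if len(crossings) == 0:
        return None
    i = crossings[0]
    f = -sd[i] / (sd[i + 1] - sd[i])
    d = depth[i] + f * (depth[i + 1] - depth[i])
    pt = s.points[i] + f * (s.points[i + 1] - s.points[i])
    return float(d), pt


def _interp_w(w: NormalizedDepthField, pts: np.ndarray) -> np.ndarray:
    inv = np.linalg.inv(w.affine)
    c = (np.atleast_2d(pts) @ inv[:3, :3].T + inv[:3, 3]).T
    data = np.where(w.valid, w.data, np.nan)
    return map_coordinates(data, c, order=1, mode="constant", cval=np.nan)


def thickness_map(
    s1: trimesh.Trimesh,
    metric: str,
    s_pag: trimesh.Trimesh,
    streamlines: list[Streamline] | None = None,
    w: NormalizedDepthField | None = None,
    vertices: np.ndarray | None = None,
    normals: np.ndarray | None = None,
) -> np.ndarray:
    """Thickness at every S1 vertex (NaN where undefined).

    ``metric`` is ``euclidean`` (inward-normal ray to the PAG surface),
    ``streamline`` (path distance along the vertex streamline to its PAG
    crossing) or ``normalized`` (w interpolated at that crossing).
    ``normals`` should be the same outward normals used to seed the
    streamlines (the pipeline's field normals); mesh vertex normals are
    the fallback.
    """
    if metric not in METRICS:
        raise ValueError(f"metric must be one of {METRICS}")
    if vertices is None:
        vertices = np.arange(len(s1.vertices))
    vertices = np.asarray(vertices, dtype=int)
    out = np.full(len(s1.vertices), np.nan)
    if metric == "euclidean":
        if normals is None:
            normals = outward_vertex_normals(s1)
        t = _ray_mesh_first_hit(
            s1.vertices[vertices], -normals[vertices], s_pag
        )
        out[vertices] = t
        return out
    if streamlines is None:
        raise ValueError(f"metric {metric!r} requires streamlines")
    if metric == "normalized" and w is None:
        raise ValueError("normalized metric requires the w field")
    md = _MeshDistance(s_pag)
    want = set(int(v) for v in vertices)
    chosen = [s for s in streamlines if s.origin_vertex in want and s.complete]
    if not chosen:
        return out
    # one batched signed-distance query over all streamline points
    counts = [len(s.points) for s in chosen]
    sd_all = _signed_distance_to_mesh(
        np.vstack([s.points for s in chosen]), md
    )
    offsets = np.concatenate([[0], np.cumsum(counts)])
    crossing_pts = []
    crossing_vertices = []
    for k, s in enumerate(chosen):
        sd = sd_all[offsets[k] : offsets[k + 1]]
        depth = s.depth_from_surface
        after = depth >= 0
        crossings = np.nonzero((sd[:-1] < 0) & (sd[1:] >= 0) & after[1:])[0]
        if len(crossings) == 0:
            continue
        i = crossings[0]
        f = -sd[i] / (sd[i + 1] - sd[i])
        if metric == "streamline":
            out[s.origin_vertex] = depth[i] + f * (depth[i + 1] - depth[i])
        else:
            crossing_pts.append(s.points[i] + f * (s.points[i + 1] - s.points[i]))
            crossing_vertices.append(s.origin_vertex)
    if metric == "normalized" and crossing_pts:
        out[np.array(crossing_vertices)] = _interp_w(w, np.vstack(crossing_pts))
    return out


def thickness_at(
    vertex: int,
    metric: str,
    s1: trimesh.Trimesh,
    s_pag: trimesh.Trimesh,
    streamlines: list[Streamline] | None = None,
    w: NormalizedDepthField | None = None,
    normals: np.ndarray | None = None,
) -> tuple[float, str | None]:
    """Thickness at one S1 vertex; returns (value, reason) with NaN and a
    reason string (``no_intersection`` / ``incomplete_streamline``) when the
    metric is undefined there."""
    val = thickness_map(
        s1, metric, s_pag, streamlines=streamlines, w=w,
        vertices=np.array([vertex]), normals=normals,
    )[vertex]
    if np.isfinite(val):
        return float(val), None
    if metric == "euclidean":
        return float("nan"), "no_intersection"
    sl = next((s for s in streamlines or [] if s.origin_vertex == vertex), None)
    if sl is None or not sl.complete:
        return float("nan"), "incomplete_streamline"
    return float("nan"), "no_intersection"


def smoothed_thickness(
    center_vertex: int,
    s1: trimesh.Trimesh,
    values: np.ndarray,
    radius_mm: float = SMOOTHING_RADIUS_MM,
    fwhm_mm: float = SMOOTHING_FWHM_MM,
    graph=None,
) -> float:
    """Gaussian manifold-distance weighted thickness at a landmark.

    Weights A_n = exp(-d_m^2 / 2 sigma^2) / (sigma sqrt(2 pi)) with
    sigma = FWHM / (2 sqrt(2 ln 2)) over vertices within ``radius_mm`` of
    manifold distance; T = sum(A_n t_n) / sum(A_n).
    """
    if graph is None:
        graph = edge_graph(s1)
    dist = geodesic_distances(s1, [center_vertex], limit=radius_mm, graph=graph)
    idx = np.nonzero(np.isfinite(dist) & np.isfinite(values))[0]
    if len(idx) == 0:
        raise ValueError("no finite thickness values within the kernel radius")
    sigma = fwhm_mm / (2.0 * np.sqrt(2.0 * np.log(2.0)))
    A = np.exp(-dist[idx] ** 2 / (2 * sigma**2)) / (sigma * np.sqrt(2 * np.pi))
    return float(np.sum(A * values[idx]) / np.sum(A))


def thickness_report(
    landmarks: LandmarkSet,
    s1: trimesh.Trimesh,
    s_pag: trimesh.Trimesh,
    streamlines: list[Streamline],
    w: NormalizedDepthField,
    normals: np.ndarray | None = None,
) -> pd.DataFrame:
    """Smoothed thickness at all six landmarks under all three metrics.

    Rows are metrics, columns the landmark names -- the layout used for
    group morphometry tables.
    """
    graph = edge_graph(s1)
    rows = {}
    for metric in METRICS:
        vals = thickness_map(
            s1, metric, s_pag, streamlines=streamlines, w=w, normals=normals
        )
        rows[metric] = {
            name: smoothed_thickness(landmarks.vertices[name], s1, vals, graph=graph)
            for name in LANDMARK_NAMES
        }
    return pd.DataFrame(rows).T[list(LANDMARK_NAMES)]
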