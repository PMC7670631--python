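"""Gradient stencils, tracing, termination heuristics, path-depth regridding."""

import numpy as np
import pytest

from tectum.depth_field import NormalizedDepthField
from tectum.streamline import (
    GradientField,
    TraceParams,
    delta_d_at_depth,
    deviation_delta_d,
    gradient_field,
    levelset_depth_volume,
    trace_streamlines,
    Streamline,
)
from tectum.volume_io import ScalarVolume


def _w_field(data, affine=None, valid=None):
    affine = np.eye(4) if affine is None else affine
    valid = np.isfinite(data) if valid is None else valid
    return NormalizedDepthField(
        volume=ScalarVolume(data=data, affine=affine), valid=valid
    )


class TestGradient:
    def test_linear_field_exact(self):
        ax = np.arange(20, dtype=float)
        X = np.meshgrid(ax, ax, ax, indexing="ij")[0]
        g = gradient_field(_w_field(3.0 * X), smooth_sigma_voxels=0)
        core = g.data[4:-4, 4:-4, 4:-4]
        np.testing.assert_allclose(core[..., 0], 3.0, atol=1e-10)
        np.testing.assert_allclose(core[..., 1:], 0.0, atol=1e-10)

    def test_quadratic_stencil_value(self):
        # f = x^2: five-point stencil gives f'(2) = 4 exactly
        ax = np.arange(9, dtype=float)
        X = np.meshgrid(ax, ax, ax, indexing="ij")[0]
        g = gradient_field(_w_field(X**2), smooth_sigma_voxels=0)
        assert g.data[2, 4, 4, 0] == pytest.approx(4.0)

    def test_smoothing_preserves_quadratic_derivative(self):
        ax = np.arange(15, dtype=float)
        X = np.meshgrid(ax, ax, ax, indexing="ij")[0]
        g = gradient_field(_w_field(X**2), smooth_sigma_voxels=1.5)
        assert g.data[7, 7, 7, 0] == pytest.approx(14.0, rel=1e-3)

    def test_sphere_gradient_radial(self, sphere_small):
        dm = sphere_small["dm"]
        vol = sphere_small["vol"]
        Xw = vol.grid_world_coordinates()
        r = np.linalg.norm(Xw, axis=-1)
        sel = (r > 4.5) & (r < 8.5) & dm.grad.valid
        g = dm.grad.data[sel]
        radial = -Xw[sel] / r[sel][:, None]
        cos = np.einsum(
            "ij,ij->i", g / np.linalg.norm(g, axis=1, keepdims=True), radial
        )
        assert np.degrees(np.arccos(np.clip(cos, -1, 1))).max() < 5.0

    def test_masked_where_stencil_touches_invalid(self):
        data = np.ones((12, 12, 12))
        valid = np.ones((12, 12, 12), bool)
        valid[6, 6, 6] = False
        g = gradient_field(_w_field(data, valid=valid), smooth_sigma_voxels=0)
        assert not g.valid[4, 6, 6] and not g.valid[8, 6, 6]
        assert g.valid[3, 6, 6]


def _ramp_setup(n=41, slope=0.02):
    """w rising along +x from 0 at the left margin; gradient supplied."""
    ax = np.arange(n, dtype=float)
    X = np.meshgrid(ax, ax, ax, indexing="ij")[0]
    w = _w_field(slope * X)
    gdata = np.zeros((n, n, n, 3))
    gdata[..., 0] = slope
    grad = GradientField(data=gdata, affine=np.eye(4), valid=np.ones((n, n, n), bool))
    return w, grad, X


class TestTerminationHeuristics:
    def test_planted_angle_flip(self):
        w, grad, X = _ramp_setup()
        grad.data[X >= 20] = [0.0, 0.02, 0.0]  # 90 degree turn mid-ramp
        # unit steps so the interpolated turn is crossed in a single step
        lines = trace_streamlines(
            np.array([[2.0, 20.0, 20.0]]), np.array([[-1.0, 0.0, 0.0]]), grad, w,
            TraceParams(step_voxels=1.0),
        )
        assert lines[0].status == "terminated_angle"
        assert lines[0].points[-1, 0] < 22.0  # stopped at the flip plane

    def test_planted_plateau_stagnates(self):
        w, grad, X = _ramp_setup()
        grad.data[X >= 15] = 0.0
        lines = trace_streamlines(
            np.array([[2.0, 20.0, 20.0]]), np.array([[-1.0, 0.0, 0.0]]), grad, w
        )
        assert lines[0].status == "stagnated"

    def test_max_iter_cap(self):
        w, grad, _ = _ramp_setup()
        lines = trace_streamlines(
            np.array([[2.0, 20.0, 20.0]]),
            np.array([[-1.0, 0.0, 0.0]]),
            grad,
            w,
            TraceParams(max_iter_pos=1),
        )
        assert lines[0].status == "max_iter"

    def test_completion_on_steep_ramp(self):
        w, grad, _ = _ramp_setup(slope=0.06)  # reaches w=1 within the cap
        lines = trace_streamlines(
            np.array([[2.0, 20.0, 20.0]]), np.array([[-1.0, 0.0, 0.0]]), grad, w
        )
        assert lines[0].status == "complete"
        assert np.nanmax(lines[0].w_values) >= 1.0


class TestSphereTracing:
    def test_all_complete_and_radial(self, sphere_small):
        dm = sphere_small["dm"]
        frac = np.mean([s.complete for s in dm.streamlines])
        assert frac >= 0.95

    def test_path_distance_monotone_and_step_bounded(self, sphere_small):
        dm = sphere_small["dm"]
        step = 0.25 * 0.7
        for s in dm.streamlines[::500]:
            assert np.all(np.diff(s.path_distance) >= 0)
            assert np.all(np.diff(s.path_distance) <= step + 1e-9)

    def test_w_monotone_on_positive_segment(self, sphere_small):
        # monotone up to the aqueduct; past w = 1 the trajectory may
        # overshoot the central w maximum before terminating
        dm = sphere_small["dm"]
        for s in dm.streamlines[::500]:
            wpos = s.w_values[s.origin_index :]
            wpos = wpos[np.isfinite(wpos)]
            wpos = wpos[wpos <= 1.0]
            assert np.all(np.diff(wpos) > -5e-3)

    def test_path_at_least_straight_line(self, sphere_small):
        dm = sphere_small["dm"]
        ratios = []
        for s in dm.streamlines[::50]:
            if not s.complete:
                continue
            path = s.path_distance[-1] - s.path_distance[s.origin_index]
            chord = np.linalg.norm(s.points[-1] - s.points[s.origin_index])
            ratios.append(path / chord)
        ratios = np.array(ratios)
        assert np.all(ratios >= 1.0 - 1e-9)
        assert np.median(ratios) < 1.01  # near-equality on the sphere

    def test_streamlines_do_not_cross(self, sphere_small):
        # one-to-one S1 -> S2 association: distinct complete streamlines
        # stay separated at matched w
        dm = sphere_small["dm"]
        comp = [s for s in dm.streamlines if s.complete][:40]
        for a, b in zip(comp[:-1], comp[1:]):
            for wq in (0.25, 0.5, 0.75):
                pa = _point_at_w(a, wq)
                pb = _point_at_w(b, wq)
                if pa is None or pb is None:
                    continue
                assert np.linalg.norm(pa - pb) > 1e-3


def _point_at_w(s, wq):
    w = s.w_values
    idx = np.nonzero((w[:-1] < wq) & (w[1:] >= wq))[0]
    if len(idx) == 0:
        return None
    i = idx[0]
    f = (wq - w[i]) / (w[i + 1] - w[i])
    return s.points[i] + f * (s.points[i + 1] - s.points[i])


class TestDepthVolume:
    def test_radial_depth_recovery(self, sphere_small):
        dm = sphere_small["dm"]
        vol = sphere_small["vol"]
        truth = sphere_small["truth"]
        dv = levelset_depth_volume(dm.streamlines, vol, fill_mask=(vol.data > 0))
        r = np.linalg.norm(vol.grid_world_coordinates(), axis=-1)
        shell = (r > 3.7) & (r < 9.3)
        err = np.abs(dv.data - truth["depth"](r))[shell]
        assert np.nanmean(err) < 0.15
        assert np.nanpercentile(err, 95) < 0.3

    def test_depth_plateaus_at_ca(self, sphere_small):
        dm = sphere_small["dm"]
        vol = sphere_small["vol"]
        dv = levelset_depth_volume(dm.streamlines, vol, fill_mask=(vol.data > 0))
        r = np.linalg.norm(vol.grid_world_coordinates(), axis=-1)
        inside_ca = np.isfinite(dv.data) & (r < 2.0)
        if inside_ca.any():
            assert dv.data[inside_ca].max() <= 7.0 + 0.3

    def test_no_complete_streamlines_errors(self, sphere_small):
        vol = sphere_small["vol"]
        s = Streamline(
            points=np.zeros((2, 3)),
            w_values=np.array([0.0, 0.1]),
            path_distance=np.array([0.0, 0.1]),
            origin_vertex=0,
            origin_index=0,
            status="max_iter",
        )
        with pytest.raises(ValueError, match="complete"):
            levelset_depth_volume([s], vol)


class TestDeltaD:
    def test_quarter_circle_closed_form(self):
        # arc of radius 5 starting at the origin with tangent +x:
        # delta-d at arc length s is 5 (1 - cos(s/5)) about the +x line
        phi = np.linspace(0, np.pi / 2, 50)
        pts = np.column_stack([5 * np.sin(phi), 5 * (1 - np.cos(phi)), 0 * phi])
        seg = np.linalg.norm(np.diff(pts, axis=0), axis=1)
        s = Streamline(
            points=pts,
            w_values=np.linspace(0, 1.2, 50),
            path_distance=np.concatenate([[0], np.cumsum(seg)]),
            origin_vertex=0,
            origin_index=0,
            status="complete",
        )
        dd = deviation_delta_d(s, np.array([1.0, 0.0, 0.0]))
        np.testing.assert_allclose(dd, 5 * (1 - np.cos(phi)), atol=1e-8)

    def test_sphere_delta_d_small_at_profile_depths(self, sphere_small):
        dm = sphere_small["dm"]
        for depth in (1.0, 2.0, 3.0):
            dd = delta_d_at_depth(dm.streamlines, dm.normals, depth)
            assert np.nanmax(dd) < 0.1  # well under a voxel

    def test_table_export_shape(self):
        from tectum.streamline import streamlines_to_table

        pts = np.column_stack([np.linspace(0, 2, 5), np.zeros(5), np.zeros(5)])
        s = Streamline(
            points=pts,
            w_values=np.linspace(0, 1.2, 5),
            path_distance=np.linspace(0, 2, 5),
            origin_vertex=3,
            origin_index=1,
            status="complete",
        )
        df = streamlines_to_table([s, s])
        assert len(df) == 10
        assert df["depth_mm"].iloc[1] == 0.0  # origin index

    def test_empty_streamline_rejected(self):
        s = Streamline(
            points=np.zeros((0, 3)),
            w_values=np.zeros(0),
            path_distance=np.zeros(0),
            origin_vertex=0,
            origin_index=0,
            status="complete",
        )
        with pytest.raises(ValueError):
            deviation_delta_d(s, np.array([1.0, 0, 0]))
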