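"""PAG boundary machinery: probability profiles, U statistic, CA axis,
elliptical fitting and 3D reconstruction."""

import numpy as np
import pytest

from tectum.pag import (
    UncertaintyCurve,
    bin_uncertainty_by_probability,
    ca_axis,
    fit_ellipse_stack,
    optimize_threshold,
    probability_depth_profile,
    reconstruct_and_compare,
    spatial_uncertainty,
    surface_separation,
)
from tectum.kernels import build_kernels
from tectum.phantom import PhantomSpec, make_probability_map
from tectum.volume_io import LabelVolume, ScalarVolume


@pytest.fixture(scope="module")
def small_prob_setup(sphere_small):
    dm = sphere_small["dm"]
    vol = sphere_small["vol"]
    rng = np.random.default_rng(1)
    roi = rng.choice(len(dm.s1.vertices), 200, replace=False)
    kernels = build_kernels(
        dm.s1, vol, streamlines=dm.streamlines, radius=0.7, vertices=roi
    )
    return {"dm": dm, "vol": vol, "kernels": kernels}


class TestProbabilityProfile:
    def test_constant_probability(self, small_prob_setup):
        vol = small_prob_setup["vol"]
        P = ScalarVolume(
            data=np.ones(vol.shape), affine=vol.affine, units="probability"
        )
        prof = probability_depth_profile(
            small_prob_setup["kernels"], P, small_prob_setup["dm"].d2
        )
        assert np.allclose(prof.mean[prof.n_subjects_per_bin > 0], 1.0)

    def test_logistic_annulus_recovered(self, small_prob_setup, sphere_small):
        spec = sphere_small["spec"]
        vol = small_prob_setup["vol"]
        pmaps, _ = make_probability_map(
            spec, vol, n_subjects=1, seed=0, boundary=6.0, edge_sharpness=0.5
        )
        prof = probability_depth_profile(
            small_prob_setup["kernels"], pmaps, small_prob_setup["dm"].d2,
            max_distance=6.0,
        )
        sel = (prof.n_subjects_per_bin > 0) & (prof.distance_mm > 0.5) & (
            prof.distance_mm < 5.5
        )
        # boundary planted at radius 6 = 3 mm from the aqueduct surface
        expect = 1.0 / (1.0 + np.exp((prof.distance_mm[sel] - 3.0) / 0.5))
        rms = np.sqrt(np.nanmean((prof.mean[sel] - expect) ** 2))
        assert rms < 0.02

    def test_identical_subjects_zero_sd(self, small_prob_setup, sphere_small):
        spec = sphere_small["spec"]
        vol = small_prob_setup["vol"]
        pmaps, _ = make_probability_map(
            spec, vol, n_subjects=3, seed=0, boundary=6.0, subject_jitter=0.0
        )
        prof = probability_depth_profile(
            small_prob_setup["kernels"], pmaps, small_prob_setup["dm"].d2
        )
        assert np.nanmax(prof.sd) == pytest.approx(0.0, abs=1e-12)


class TestSpatialUncertainty:
    def test_identical_subjects_zero_U(self, small_prob_setup, sphere_small):
        spec = sphere_small["spec"]
        vol = small_prob_setup["vol"]
        pmaps, _ = make_probability_map(
            spec, vol, n_subjects=4, seed=0, boundary=6.0, subject_jitter=0.0
        )
        prof = probability_depth_profile(
            small_prob_setup["kernels"], pmaps, small_prob_setup["dm"].d2,
            max_distance=6.0,
        )
        U = spatial_uncertainty(prof)
        assert np.nanmax(U.U) == pytest.approx(0.0, abs=1e-9)

    def test_doubling_jitter_doubles_U(self, small_prob_setup, sphere_small):
        spec = sphere_small["spec"]
        vol = small_prob_setup["vol"]
        vals = []
        for sj in (0.15, 0.30):
            pmaps, _ = make_probability_map(
                spec, vol, n_subjects=12, seed=7, boundary=6.0,
                edge_sharpness=1.0, subject_jitter=sj,
            )
            prof = probability_depth_profile(
                small_prob_setup["kernels"], pmaps, small_prob_setup["dm"].d2,
                max_distance=6.5,
            )
            U = spatial_uncertainty(prof)
            sel = np.isfinite(U.U) & (U.P > 0.5) & (U.P < 0.9)
            vals.append(np.nanmean(U.U[sel] * U.P[sel]))
        assert vals[1] / vals[0] == pytest.approx(2.0, rel=0.1)

    def test_single_subject_rejected(self, small_prob_setup, sphere_small):
        spec = sphere_small["spec"]
        vol = small_prob_setup["vol"]
        pmaps, _ = make_probability_map(spec, vol, n_subjects=1, seed=0, boundary=6.0)
        prof = probability_depth_profile(
            small_prob_setup["kernels"], pmaps, small_prob_setup["dm"].d2
        )
        with pytest.raises(ValueError, match="2 subjects"):
            spatial_uncertainty(prof)


class TestOptimizeThreshold:
    def _curve(self, P, U, n=12):
        return UncertaintyCurve(
            P=np.asarray(P, dtype=float),
            U=np.asarray(U, dtype=float),
            n_subjects_per_bin=np.full(len(P), n),
            distance_mm=np.linspace(3, 1, len(P)),
        )

    def test_planted_parabola_argmin(self):
        P = np.linspace(0.5, 0.99, 25)
        assert optimize_threshold(self._curve(P, (P - 0.9) ** 2)) == pytest.approx(
            0.9, abs=0.02
        )

    def test_flat_curve_tie_breaks_high(self):
        P = np.linspace(0.5, 0.95, 10)
        assert optimize_threshold(self._curve(P, np.ones(10))) == pytest.approx(0.95)

    def test_too_few_points_rejected(self):
        P = np.array([0.5, 0.6, 0.7])
        with pytest.raises(ValueError):
            optimize_threshold(self._curve(P, P))

    def test_low_coverage_bins_excluded(self):
        P = np.linspace(0.5, 0.95, 10)
        U = np.linspace(1.0, 0.1, 10)  # minimum at the top bin...
        curve = self._curve(P, U)
        curve.n_subjects_per_bin[-1] = 2  # ...which lacks subject coverage
        assert optimize_threshold(curve) == pytest.approx(P[-2])


def _tube_label(voxel=0.7, r_lr=1.1, r_dv=2.2, half_len=10.0, pad=3.0):
    half = np.array([r_lr + pad, r_dv + pad, half_len + pad])
    n = (2 * np.ceil(half / voxel).astype(int)) + 1
    ax = [(np.arange(k) - k // 2) * voxel for k in n]
    X, Y, Z = np.meshgrid(*ax, indexing="ij")
    data = np.zeros(X.shape, dtype=np.int16)
    data[((X / r_lr) ** 2 + (Y / r_dv) ** 2 <= 1) & (np.abs(Z) <= half_len)] = 2
    affine = np.eye(4)
    affine[:3, :3] *= voxel
    affine[:3, 3] = [-(k // 2) * voxel for k in n]
    return LabelVolume(data=data, affine=affine)


class TestCaAxis:
    def test_straight_tube_centerline(self):
        axis = ca_axis(_tube_label())
        assert np.abs(axis.points[:, :2]).max() < 0.35  # half an upsampled voxel
        assert np.allclose(np.abs(axis.tangents[:, 2]), 1.0, atol=0.05)

    def test_curved_tube_arclength(self):
        # quarter-circle tube of radius 8 in the x-z plane
        voxel = 0.5
        n = 61
        ax = [(np.arange(n) - n // 2) * voxel] * 3
        X, Y, Z = np.meshgrid(*ax, indexing="ij")
        r = np.sqrt((X + 8) ** 2 + (Z + 8) ** 2)
        angle = np.arctan2(Z + 8, X + 8)
        data = np.zeros(X.shape, dtype=np.int16)
        data[
            (np.abs(r - 8) ** 2 + Y**2 <= 1.2**2)
            & (angle >= 0.05) & (angle <= np.pi / 2 - 0.05)
        ] = 2
        affine = np.eye(4)
        affine[:3, :3] *= voxel
        affine[:3, 3] = -(n // 2) * voxel
        axis = ca_axis(LabelVolume(data=data, affine=affine))
        # thinning erodes roughly a tube radius at each end, so compare
        # against the analytic arc over the angular span actually recovered
        ang = np.arctan2(axis.points[:, 2] + 8, axis.points[:, 0] + 8)
        span = ang.max() - ang.min()
        assert span > 0.8 * (np.pi / 2 - 0.1)
        assert axis.arclength[-1] == pytest.approx(8 * span, rel=0.05)
        # centerline sits on the planted circle of radius 8
        r = np.sqrt((axis.points[:, 0] + 8) ** 2 + (axis.points[:, 2] + 8) ** 2)
        assert np.abs(r - 8).max() < 0.5

    def test_disconnected_rejected(self):
        vol = _tube_label()
        data = vol.data.copy()
        data[:, :, data.shape[2] // 2] = 0
        with pytest.raises(ValueError, match="components"):
            ca_axis(LabelVolume(data=data, affine=vol.affine))


class TestEllipseStack:
    def test_circular_annulus(self, annulus):
        spec, vol, axis = annulus["spec"], annulus["vol"], annulus["axis"]
        pmaps, _ = make_probability_map(
            spec, vol, n_subjects=1, seed=0, boundary=(2.5, 2.5), edge_sharpness=0.3
        )
        fits = [
            f
            for f in fit_ellipse_stack(pmaps[0], axis, 0.5, slice_extent=6.0)
            if 1.0 < f.arclength < axis.arclength[-1] - 1.0
        ]
        assert np.mean([f.a for f in fits]) == pytest.approx(2.5, abs=0.1)
        assert np.mean([f.b for f in fits]) == pytest.approx(2.5, abs=0.1)
        assert np.mean([f.epsilon for f in fits]) == pytest.approx(1.0, abs=0.03)

    def test_planted_ellipse_and_noise_floor(self, annulus):
        spec, vol, axis = annulus["spec"], annulus["vol"], annulus["axis"]
        pmaps, _ = make_probability_map(
            spec, vol, n_subjects=1, seed=2, boundary=(3.0, 2.0),
            edge_sharpness=0.3, radial_noise_sd=0.1,
        )
        fits = [
            f
            for f in fit_ellipse_stack(pmaps[0], axis, 0.5, slice_extent=6.0)
            if 1.0 < f.arclength < axis.arclength[-1] - 1.0
        ]
        assert np.mean([f.a for f in fits]) == pytest.approx(3.0, abs=0.1)
        assert np.mean([f.b for f in fits]) == pytest.approx(2.0, abs=0.1)
        assert np.mean([f.epsilon for f in fits]) == pytest.approx(2 / 3, abs=0.02)
        # rms residual tracks the planted radial noise
        assert np.mean([f.rms for f in fits]) == pytest.approx(0.1, abs=0.05)

    def test_bad_threshold_rejected(self, annulus):
        with pytest.raises(ValueError):
            fit_ellipse_stack(
                ScalarVolume(
                    data=np.zeros(annulus["vol"].shape), affine=annulus["vol"].affine
                ),
                annulus["axis"],
                1.5,
            )


class TestReconstruction:
    def test_identity_separation_zero(self, annulus):
        import trimesh

        mesh = trimesh.creation.icosphere(2, radius=3.0)
        stats = surface_separation(mesh, mesh.copy())
        assert stats["mean"] == pytest.approx(0.0, abs=1e-9)
        assert stats["fraction_gt_2mm"] == 0.0

    def test_elliptical_tube_reconstruction(self, annulus):
        spec, vol, axis = annulus["spec"], annulus["vol"], annulus["axis"]
        a, b = 3.0, 2.0
        pmaps, _ = make_probability_map(
            spec, vol, n_subjects=1, seed=5, boundary=(a, b), edge_sharpness=0.3
        )
        fits = fit_ellipse_stack(pmaps[0], axis, 0.5, slice_extent=6.0)
        mesh, _ = reconstruct_and_compare(fits, axis, vol)
        v = np.asarray(mesh.vertices)
        mid = np.abs(v[:, 2]) < 4.0
        theta = np.arctan2(v[mid, 1], v[mid, 0])
        rho = a * b / np.sqrt((b * np.cos(theta)) ** 2 + (a * np.sin(theta)) ** 2)
        res = np.abs(np.linalg.norm(v[mid, :2], axis=1) - rho)
        assert res.mean() < 0.5 * spec.voxel

    def test_too_few_fits_rejected(self, annulus):
        with pytest.raises(ValueError, match="3"):
            reconstruct_and_compare([], annulus["axis"], annulus["vol"])

    def test_ellipse_table_columns(self):
        from tectum.pag import EllipseFit, ellipse_table

        fit = EllipseFit(
            axis_index=0, arclength=1.0, center=np.zeros(3), a=3.0, b=2.0,
            rotation=0.01, rms=0.1, n_points=40,
        )
        df = ellipse_table([fit, fit])
        assert df["epsilon"].iloc[0] == pytest.approx(2 / 3)
        assert len(df) == 2
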