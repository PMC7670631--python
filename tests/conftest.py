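"""Shared phantom fixtures.

Heavy pipeline products are session-scoped so the sphere and tube
phantoms are built once and reused across test modules.
"""

from __future__ import annotations

import numpy as np
import pytest
import trimesh

from tectum.kernels import build_kernels
from tectum.phantom import (
    PhantomSpec,
    make_concentric_spheres,
    make_eccentric_spheres,
    make_midbrain_tube,
)
from tectum.pipeline import depth_maps
from tectum.streamline import levelset_depth_volume


@pytest.fixture(scope="session")
def sphere_small():
    """Concentric-sphere phantom at reduced scale (R1=10, R2=3, 0.7 mm)."""
    spec = PhantomSpec(R1=10.0, R2=3.0, voxel=0.7, margin_voxels=8)
    vol, truth = make_concentric_spheres(spec)
    dm = depth_maps(vol)
    return {"spec": spec, "vol": vol, "truth": truth, "dm": dm}


@pytest.fixture(scope="session")
def sphere_big():
    """Full-scale concentric-sphere phantom (R1=20, R2=4, 0.7 mm, ~96^3)."""
    spec = PhantomSpec()
    vol, truth = make_concentric_spheres(spec)
    dm = depth_maps(vol)
    depth_vol = levelset_depth_volume(dm.streamlines, vol, fill_mask=(vol.data > 0))
    return {"spec": spec, "vol": vol, "truth": truth, "dm": dm, "depth_vol": depth_vol}


@pytest.fixture(scope="session")
def sphere_big_kernels(sphere_big):
    """Streamline depth kernels (0.7 mm manifold radius) on the big phantom."""
    return build_kernels(
        sphere_big["dm"].s1,
        sphere_big["vol"],
        streamlines=sphere_big["dm"].streamlines,
        radius=0.7,
        depth_volumes={"levelset_path": sphere_big["depth_vol"]},
    )


@pytest.fixture(scope="session")
def eccentric():
    """Eccentric-sphere phantom with a concentric-to-CA 6 mm PAG sphere."""
    spec = PhantomSpec(kind="eccentric_spheres", offset=(0.0, 0.0, 2.0), margin_voxels=8)
    vol, truth = make_eccentric_spheres(spec)
    dm = depth_maps(vol)
    c_pag = np.array([0.0, 0.0, 2.0])
    s_pag = trimesh.creation.icosphere(4, radius=6.0)
    s_pag.vertices = s_pag.vertices + c_pag
    from tectum.thickness import thickness_map

    te = thickness_map(dm.s1, "euclidean", s_pag, normals=dm.normals)
    ts = thickness_map(dm.s1, "streamline", s_pag, streamlines=dm.streamlines)
    tw = thickness_map(dm.s1, "normalized", s_pag, streamlines=dm.streamlines, w=dm.w)
    return {
        "spec": spec,
        "vol": vol,
        "truth": truth,
        "dm": dm,
        "s_pag": s_pag,
        "c_pag": c_pag,
        "r_pag": 6.0,
        "te": te,
        "ts": ts,
        "tw": tw,
    }


@pytest.fixture(scope="session")
def tube():
    """Bumped midbrain-tube phantom with x2-upsampled surfaces."""
    from tectum.surface_model import extract_isosurface, refine_surface
    from tectum.volume_io import upsample_labels

    spec = PhantomSpec(kind="midbrain_tube")
    vol, truth = make_midbrain_tube(spec)
    up = upsample_labels(vol, 2)
    # refinement iterations scale with mesh resolution: the x2
    # upsampled mesh needs ~4x the iterations for the same smoothing length
    s1 = refine_surface(extract_isosurface(up, (1, 2, 3)), 10)
    s2 = refine_surface(extract_isosurface(up, 2), 10)
    return {"spec": spec, "vol": vol, "truth": truth, "s1": s1, "s2": s2}


@pytest.fixture(scope="session")
def annulus():
    """Hi-res flat tube for elliptical-annulus boundary fitting."""
    from tectum.pag import ca_axis

    spec = PhantomSpec(
        kind="midbrain_tube",
        voxel=0.35,
        slab_half_x=5.0,
        slab_y=(-5.0, 4.0),
        slab_half_z=9.0,
        tube_half_length=7.0,
        bump_amplitude=0.0,
    )
    vol, truth = make_midbrain_tube(spec)
    axis = ca_axis(vol)
    return {"spec": spec, "vol": vol, "truth": truth, "axis": axis}
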