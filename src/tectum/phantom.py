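"""Synthetic midbrain-like phantoms with analytic ground truth.

Three geometries stand in for subject segmentations so every pipeline
stage is testable end to end:

* concentric spheres -- outer "brainstem" shell of radius R1 around an
  inner "aqueduct" ball of radius R2, where the level-set depth has the
  closed form w(r) = (R1 - r) / (R1 - R2) and path depth is R1 - r;
* eccentric spheres -- the inner ball displaced, breaking the radial
  symmetry while keeping line-sphere oracles computable;
* midbrain tube -- a tissue slab whose dorsal surface carries four
  Gaussian hillocks (two rostro-caudal pairs, mimicking the colliculi)
  separated by a transverse groove, with an elliptical "aqueduct" tube
  running through the slab.

Probability-map and activation generators plant logistic boundary edges
and depth-localized Gaussian responses with known parameters.  All
generators are deterministic given (spec, seed).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from tectum.volume_io import (
    LABEL_AQUEDUCT,
    LABEL_BRAINSTEM,
    LABEL_COLLICULUS,
    LabelVolume,
    ScalarVolume,
)


@dataclass
class PhantomSpec:
    """Geometry and sampling parameters for the synthetic phantoms (mm).

    The default voxel size (0.7 mm isotropic) matches high-resolution 3T
    anatomy; ``voxel=0.35`` gives the hi-res regime used for the small
    elliptical-annulus fits.
    """

    kind: str = "concentric_spheres"
    # spheres
    R1: float = 20.0
    R2: float = 4.0
    offset: tuple[float, float, float] = (0.0, 0.0, 0.0)
    # midbrain tube: two rostro-caudal pairs of hillocks close enough that
    # the collicular patch is contiguous across the transverse groove
    slab_half_x: float = 13.0
    slab_y: tuple[float, float] = (-8.0, 6.0)
    slab_half_z: float = 15.0
    tube_radius_lr: float = 1.1
    tube_radius_dv: float = 2.2
    tube_half_length: float = 13.0
    bump_amplitude: float = 3.0
    bump_sigma: float = 2.0
    bump_x: float = 4.5
    bump_z: float = 5.0
    trench_amplitude: float = 1.2
    trench_sigma: float = 1.8
    # sampling
    voxel: float = 0.7
    margin_voxels: int = 19
    #: world-mm shift of the voxel grid relative to the geometry; the
    #: anatomy stays put while the sampling lattice moves (sub-voxel
    #: offsets re-rasterize the phantom, for stability tests)
    grid_offset: tuple[float, float, float] = (0.0, 0.0, 0.0)
    noise_sd: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not (self.R1 > self.R2 > 0):
            raise ValueError("need R1 > R2 > 0")
        if self.voxel <= 0:
            raise ValueError("voxel size must be positive")


def _centered_grid(half_extent_mm: np.ndarray, voxel: float, offset=(0.0, 0.0, 0.0)):
    """Isotropic grid with the world origin near the central voxel center."""
    half_n = np.ceil(np.asarray(half_extent_mm) / voxel).astype(int)
    shape = 2 * half_n + 1
    affine = np.eye(4)
    affine[:3, :3] *= voxel
    affine[:3, 3] = -half_n * voxel + np.asarray(offset, dtype=float)
    axes = [(np.arange(n) * voxel + affine[k, 3]) for k, n in enumerate(shape)]
    X, Y, Z = np.meshgrid(*axes, indexing="ij")
    return X, Y, Z, affine


def _sphere_labels(spec: PhantomSpec, offset) -> tuple[LabelVolume, dict]:
    off = np.asarray(offset, dtype=float)
    if np.linalg.norm(off) + spec.R2 >= spec.R1:
        raise ValueError("inner sphere is not strictly inside the outer sphere")
    half = spec.R1 + spec.margin_voxels * spec.voxel
    X, Y, Z, affine = _centered_grid(np.full(3, half), spec.voxel, spec.grid_offset)
    r_out = np.sqrt(X**2 + Y**2 + Z**2)
    r_in = np.sqrt((X - off[0]) ** 2 + (Y - off[1]) ** 2 + (Z - off[2]) ** 2)
    data = np.zeros(X.shape, dtype=np.int16)
    data[r_out < spec.R1] = LABEL_BRAINSTEM
    data[r_in < spec.R2] = LABEL_AQUEDUCT
    if (data[0].any() or data[-1].any() or data[:, 0].any() or data[:, -1].any()
            or data[:, :, 0].any() or data[:, :, -1].any()):
        raise ValueError("sphere touches the grid boundary; increase margin")
    vol = LabelVolume(data=data, affine=affine)

    R1, R2 = spec.R1, spec.R2

    def w_oracle(r):
        return (R1 - np.asarray(r, dtype=float)) / (R1 - R2)

    def depth_oracle(r):
        return np.clip(R1 - np.asarray(r, dtype=float), 0.0, R1 - R2)

    truth = {
        "R1": R1,
        "R2": R2,
        "offset": off,
        "w": w_oracle,
        "depth": depth_oracle,
        "seed": spec.seed,
    }
    return vol, truth


def make_concentric_spheres(spec: PhantomSpec | None = None) -> tuple[LabelVolume, dict]:
    """Shell phantom: BS = {R2 < r < R1}, CA = {r < R2}, both centered.

    Returns the label volume and analytic oracles ``truth["w"](r)`` and
    ``truth["depth"](r)``.
    """
    spec = spec or PhantomSpec(kind="concentric_spheres")
    return _sphere_labels(spec, (0.0, 0.0, 0.0))


def make_eccentric_spheres(spec: PhantomSpec | None = None) -> tuple[LabelVolume, dict]:
    """Shell phantom with the inner ball displaced by ``spec.offset``."""
    spec = spec or PhantomSpec(kind="eccentric_spheres", offset=(0.0, 0.0, 2.0))
    return _sphere_labels(spec, spec.offset)


def _dorsal_height(spec: PhantomSpec, x, z):
    """Height of the dorsal surface above the slab base plane (y units)."""
    h = np.full(np.broadcast(x, z).shape, float(spec.slab_y[1]))
    for sx in (-1.0, 1.0):
        for sz in (-1.0, 1.0):
            h = h + spec.bump_amplitude * np.exp(
                -((x - sx * spec.bump_x) ** 2 + (z - sz * spec.bump_z) ** 2)
                / (2 * spec.bump_sigma**2)
            )
    h = h - spec.trench_amplitude * np.exp(-(z**2) / (2 * spec.trench_sigma**2))
    return h


def _bump_envelope(spec: PhantomSpec, x, z):
    env = np.zeros(np.broadcast(x, z).shape)
    for sx in (-1.0, 1.0):
        for sz in (-1.0, 1.0):
            env = np.maximum(
                env,
                spec.bump_amplitude
                * np.exp(
                    -((x - sx * spec.bump_x) ** 2 + (z - sz * spec.bump_z) ** 2)
                    / (2 * spec.bump_sigma**2)
                ),
            )
    return env


def _find_apexes(spec: PhantomSpec) -> dict[str, np.ndarray]:
    """World coordinates of the four hillock apices (fine-grid search)."""
    apexes = {}
    names = {(-1, 1): "SC-L", (1, 1): "SC-R", (-1, -1): "IC-L", (1, -1): "IC-R"}
    for (sx, sz), name in names.items():
        xs = np.arange(sx * spec.bump_x - 2.0, sx * spec.bump_x + 2.0, 0.02)
        zs = np.arange(sz * spec.bump_z - 2.0, sz * spec.bump_z + 2.0, 0.02)
        Xg, Zg = np.meshgrid(xs, zs, indexing="ij")
        H = _dorsal_height(spec, Xg, Zg)
        i, j = np.unravel_index(np.argmax(H), H.shape)
        apexes[name] = np.array([Xg[i, j], H[i, j], Zg[i, j]])
    return apexes


def make_midbrain_tube(spec: PhantomSpec | None = None) -> tuple[LabelVolume, dict]:
    """Slab-with-hillocks phantom around an elliptical aqueduct tube.

    The tissue slab spans ``|x| <= slab_half_x``, ``slab_y[0] <= y <= h(x, z)``
    and ``|z| <= slab_half_z`` where the dorsal height h carries four
    Gaussian hillocks in two rostro-caudal pairs plus a transverse groove
    at z = 0.  The aqueduct is an elliptical tube along z centered at the
    origin; its dorsal-ventral radius exceeds the left-right radius so the
    best-fit plane through its surface is the mid-sagittal plane.  Hillock
    caps carry the colliculus label.  Returns the label volume and a truth
    dict with the apex coordinates and tube geometry.
    """
    spec = spec or PhantomSpec(kind="midbrain_tube")
    if spec.bump_amplitude > 0:
        gap = 2 * spec.bump_x
        if gap < 2.0 * spec.bump_sigma:
            raise ValueError("hillocks overlap too strongly; separate the pairs")
    pad = 6 * spec.voxel
    half = np.array(
        [
            spec.slab_half_x + pad,
            max(abs(spec.slab_y[0]), spec.slab_y[1] + spec.bump_amplitude) + pad,
            spec.slab_half_z + pad,
        ]
    )
    X, Y, Z, affine = _centered_grid(half, spec.voxel, spec.grid_offset)
    h = _dorsal_height(spec, X, Z)
    slab = (
        (np.abs(X) <= spec.slab_half_x)
        & (Y >= spec.slab_y[0])
        & (Y <= h)
        & (np.abs(Z) <= spec.slab_half_z)
    )
    tube = (
        ((X / spec.tube_radius_lr) ** 2 + (Y / spec.tube_radius_dv) ** 2 <= 1.0)
        & (np.abs(Z) <= spec.tube_half_length)
    )
    data = np.zeros(X.shape, dtype=np.int16)
    data[slab] = LABEL_BRAINSTEM
    env = _bump_envelope(spec, X, Z)
    # collicular shell: tissue near the dorsal surface within the broad
    # footprint of the hillocks (10% of amplitude), contiguous across pairs
    coll = slab & (Y >= h - 2.0) & (env >= 0.1 * spec.bump_amplitude)
    data[coll] = LABEL_COLLICULUS
    data[tube] = LABEL_AQUEDUCT
    vol = LabelVolume(data=data, affine=affine)
    truth = {
        "apexes": _find_apexes(spec),
        "tube_center": np.array([0.0, 0.0, 0.0]),
        "tube_axis": np.array([0.0, 0.0, 1.0]),
        "tube_radii": (spec.tube_radius_lr, spec.tube_radius_dv),
        "dorsal_height": lambda x, z: _dorsal_height(spec, x, z),
        "seed": spec.seed,
    }
    return vol, truth


def _harmonic_noise(rng, n_slices: int, sd: float, n_harmonics: int = 4):
    """Per-slice smooth angular boundary perturbation with RMS ~ sd."""
    v = sd**2 / (1.0 + n_harmonics)
    a0 = rng.normal(0.0, np.sqrt(v), size=n_slices)
    ak = rng.normal(0.0, np.sqrt(v), size=(n_slices, n_harmonics))
    bk = rng.normal(0.0, np.sqrt(v), size=(n_slices, n_harmonics))
    return a0, ak, bk


def make_probability_map(
    spec: PhantomSpec,
    grid: LabelVolume | ScalarVolume,
    n_subjects: int = 1,
    seed: int = 0,
    boundary=(3.0, 2.0),
    edge_sharpness: float = 0.3,
    subject_jitter: float = 0.0,
    radial_noise_sd: float = 0.0,
    noise_sd: float | None = None,
) -> tuple[list[ScalarVolume], dict]:
    """Synthetic gray-matter probability maps with a logistic boundary edge.

    For sphere phantoms the boundary is a sphere of radius ``boundary``
    (scalar, mm) about the inner center; for the tube phantom it is an
    elliptical annulus about the tube axis with semi-axes
    ``boundary = (a_lr, b_dv)`` mm.  Probability is
    ``P = logistic(-(signed mm distance to boundary) / edge_sharpness)``:
    high inside (toward the aqueduct), 0.5 on the boundary.  Each subject's
    boundary is displaced radially by an independent N(0, subject_jitter^2)
    draw; ``radial_noise_sd`` adds a smooth per-slice angular perturbation
    (tube only).  Returns the volumes and a truth dict with per-subject
    jitters and planted semi-axes.
    """
    if edge_sharpness <= 0:
        raise ValueError("edge_sharpness must be > 0")
    rng = np.random.default_rng(seed)
    jitters = (
        rng.normal(0.0, subject_jitter, size=n_subjects)
        if subject_jitter > 0
        else np.zeros(n_subjects)
    )
    axes = [np.arange(n) for n in grid.shape]
    I, J, K = np.meshgrid(*axes, indexing="ij")
    ijk = np.column_stack([I.ravel(), J.ravel(), K.ravel()])
    world = grid.voxel_to_world(ijk).reshape(grid.shape + (3,))
    X, Y, Z = world[..., 0], world[..., 1], world[..., 2]

    if spec.kind in ("concentric_spheres", "eccentric_spheres"):
        rb = float(np.atleast_1d(boundary)[0])
        off = np.asarray(spec.offset, dtype=float)
        r = np.sqrt((X - off[0]) ** 2 + (Y - off[1]) ** 2 + (Z - off[2]) ** 2)
        signed_base = r - rb
        theta = None
        truth_axes = {"radius": rb}
    elif spec.kind == "midbrain_tube":
        a, b = float(boundary[0]), float(boundary[1])
        r2d = np.sqrt(X**2 + Y**2)
        theta = np.arctan2(Y, X)
        rho = (a * b) / np.sqrt((b * np.cos(theta)) ** 2 + (a * np.sin(theta)) ** 2)
        signed_base = r2d - rho
        truth_axes = {"a": a, "b": b}
    else:
        raise ValueError(f"unknown phantom kind {spec.kind!r}")

    if noise_sd is None:
        noise_sd = spec.noise_sd
    volumes: list[ScalarVolume] = []
    per_subject_axes = []
    for si in range(n_subjects):
        signed = signed_base - jitters[si]
        if radial_noise_sd > 0 and theta is not None:
            a0, ak, bk = _harmonic_noise(rng, grid.shape[2], radial_noise_sd)
            eta = a0[None, None, :] * np.ones_like(theta)
            for k in range(ak.shape[1]):
                eta = eta + ak[None, None, :, k] * np.cos((k + 1) * theta)
                eta = eta + bk[None, None, :, k] * np.sin((k + 1) * theta)
            signed = signed - eta
        P = 1.0 / (1.0 + np.exp(np.clip(signed / edge_sharpness, -40, 40)))
        if noise_sd and noise_sd > 0:
            P = P + rng.normal(0.0, noise_sd, size=P.shape)
        P = np.clip(P, 0.0, 1.0)
        volumes.append(
            ScalarVolume(data=P, affine=grid.affine.copy(), units="probability")
        )
        if spec.kind == "midbrain_tube":
            per_subject_axes.append(
                {"a": truth_axes["a"] + jitters[si], "b": truth_axes["b"] + jitters[si]}
            )
        else:
            per_subject_axes.append({"radius": truth_axes["radius"] + jitters[si]})
    truth = {
        "jitters": jitters,
        "boundary": truth_axes,
        "per_subject": per_subject_axes,
        "edge_sharpness": edge_sharpness,
        "seed": seed,
    }
    return volumes, truth


def make_activation(
    depth: ScalarVolume,
    depth_center: float,
    depth_sigma: float = 0.6,
    amplitude: float = 1.0,
    noise_sd: float = 0.0,
    n_runs: int = 1,
    seed: int = 0,
) -> list[ScalarVolume]:
    """Depth-localized Gaussian activation volumes with per-run noise.

    ``scalar = amplitude * exp(-(depth - center)^2 / 2 sigma^2) + noise``;
    voxels without a defined depth get pure noise.  Runs draw independent
    noise from one seeded generator.
    """
    rng = np.random.default_rng(seed)
    d = depth.data
    signal = np.where(
        np.isfinite(d),
        amplitude * np.exp(-((d - depth_center) ** 2) / (2 * depth_sigma**2)),
        0.0,
    )
    runs = []
    for _ in range(n_runs):
        data = signal + (
            rng.normal(0.0, noise_sd, size=signal.shape) if noise_sd > 0 else 0.0
        )
        runs.append(
            ScalarVolume(data=data, affine=depth.affine.copy(), units="statistic")
        )
    return runs
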