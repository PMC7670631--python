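"""Volumes with voxel-to-world affines, NIfTI io and label conventions.

All geometry in the package is computed in world millimetres through the
voxel-index -> world affine carried by every volume.  Voxel indices are
0-based and refer to voxel centers.  Label volumes follow one convention
used throughout: 0 background/CSF, 1 brainstem tissue (BS), 2 cerebral
aqueduct (CA), 3 colliculus.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import nibabel as nib
import numpy as np

LABEL_BACKGROUND = 0
LABEL_BRAINSTEM = 1
LABEL_AQUEDUCT = 2
LABEL_COLLICULUS = 3
VALID_LABELS = (LABEL_BACKGROUND, LABEL_BRAINSTEM, LABEL_AQUEDUCT, LABEL_COLLICULUS)

#: tags for :class:`ScalarVolume.units`
SCALAR_UNITS = ("mm", "probability", "dimensionless", "statistic")


def _check_affine(affine: np.ndarray) -> np.ndarray:
    affine = np.asarray(affine, dtype=float)
    if affine.shape != (4, 4):
        raise ValueError(f"affine must be 4x4, got {affine.shape}")
    if abs(np.linalg.det(affine[:3, :3])) < 1e-12:
        raise ValueError("affine is singular (zero voxel volume)")
    return affine


@dataclass
class ScalarVolume:
    """A 3D scalar field on a regular grid in world mm.

    Parameters
    ----------
    data : (ni, nj, nk) float array
    affine : (4, 4) voxel-index -> world-mm map (voxel centers at integers)
    units : one of ``mm | probability | dimensionless | statistic``
    """

    data: np.ndarray
    affine: np.ndarray
    units: str = "dimensionless"

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 3:
            raise ValueError("data must be 3D")
        self.affine = _check_affine(self.affine)
        if self.units not in SCALAR_UNITS:
            raise ValueError(f"unknown units tag {self.units!r}")
        if self.units == "probability":
            finite = self.data[np.isfinite(self.data)]
            if finite.size and (finite.min() < -1e-9 or finite.max() > 1 + 1e-9):
                raise ValueError("probability volume has values outside [0, 1]")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape

    @property
    def voxel_size(self) -> np.ndarray:
        """Edge length of a voxel along each axis (mm)."""
        return np.linalg.norm(self.affine[:3, :3], axis=0)

    @property
    def mean_voxel_edge(self) -> float:
        return float(self.voxel_size.mean())

    def voxel_to_world(self, ijk: np.ndarray) -> np.ndarray:
        ijk = np.atleast_2d(np.asarray(ijk, dtype=float))
        return ijk @ self.affine[:3, :3].T + self.affine[:3, 3]

    def world_to_voxel(self, xyz: np.ndarray) -> np.ndarray:
        xyz = np.atleast_2d(np.asarray(xyz, dtype=float))
        inv = np.linalg.inv(self.affine)
        return xyz @ inv[:3, :3].T + inv[:3, 3]

    def grid_world_coordinates(self) -> np.ndarray:
        """World coordinates of every voxel center, shape (ni, nj, nk, 3)."""
        ijk = np.stack(
            np.meshgrid(*(np.arange(n) for n in self.shape), indexing="ij"), axis=-1
        )
        return self.voxel_to_world(ijk.reshape(-1, 3)).reshape(self.shape + (3,))


@dataclass
class LabelVolume:
    """An integer segmentation volume; see module docstring for the label map."""

    data: np.ndarray
    affine: np.ndarray
    label_map: dict = field(
        default_factory=lambda: {
            LABEL_BACKGROUND: "background",
            LABEL_BRAINSTEM: "brainstem",
            LABEL_AQUEDUCT: "aqueduct",
            LABEL_COLLICULUS: "colliculus",
        }
    )

    def __post_init__(self) -> None:
        data = np.asarray(self.data)
        if data.ndim != 3:
            raise ValueError("data must be 3D")
        if not np.issubdtype(data.dtype, np.integer):
            rounded = np.rint(data)
            if not np.allclose(data, rounded, atol=1e-6):
                raise ValueError("label volume has non-integer values")
            data = rounded.astype(np.int16)
        self.data = data.astype(np.int16, copy=False)
        self.affine = _check_affine(self.affine)
        bad = sorted(set(np.unique(self.data)) - set(VALID_LABELS))
        if bad:
            raise ValueError(f"labels outside {{0..3}} present: {bad}")

    # share the geometry helpers with ScalarVolume
    shape = ScalarVolume.shape
    voxel_size = ScalarVolume.voxel_size
    mean_voxel_edge = ScalarVolume.mean_voxel_edge
    voxel_to_world = ScalarVolume.voxel_to_world
    world_to_voxel = ScalarVolume.world_to_voxel
    grid_world_coordinates = ScalarVolume.grid_world_coordinates

    def mask(self, label: int) -> np.ndarray:
        return self.data == label


Volume = ScalarVolume | LabelVolume


def load_volume(path: str | Path, expect: str = "scalar") -> Volume:
    """Load a NIfTI volume as a :class:`ScalarVolume` or :class:`LabelVolume`.

    Parameters
    ----------
    path : NIfTI-1/2 file (.nii or .nii.gz)
    expect : ``"scalar"`` or ``"label"``; label volumes are validated against
        the package label convention and loading fails if other integers are
        present.
    """
    img = nib.load(str(path))
    affine = img.affine
    if affine is None:
        raise ValueError(f"{path}: NIfTI image has no affine")
    data = np.asanyarray(img.dataobj)
    if data.ndim == 4 and data.shape[3] == 1:
        data = data[..., 0]
    if data.ndim != 3:
        raise ValueError(f"{path}: expected 3D data, got shape {data.shape}")
    if expect == "label":
        return LabelVolume(data=data, affine=affine)
    if expect == "scalar":
        units = "dimensionless"
        arr = np.asarray(data, dtype=float)
        finite = arr[np.isfinite(arr)]
        if finite.size and finite.min() >= 0 and finite.max() <= 1:
            units = "probability"
        return ScalarVolume(data=arr, affine=affine, units=units)
    raise ValueError(f"expect must be 'scalar' or 'label', got {expect!r}")


def save_volume(vol: Volume, path: str | Path) -> None:
    """Write a volume as NIfTI-1, preserving the affine."""
    data = vol.data
    if isinstance(vol, LabelVolume):
        data = data.astype(np.int16)
    else:
        data = data.astype(np.float64)
    nib.Nifti1Image(data, vol.affine).to_filename(str(path))


def upsample_labels(vol: LabelVolume, factor: int) -> LabelVolume:
    """Nearest-neighbor upsample a label volume by an integer factor.

    The affine is rescaled so world coordinates of the labelled anatomy are
    preserved: each original voxel becomes a ``factor**3`` block of voxels
    covering the same world extent.
    """
    if not isinstance(factor, (int, np.integer)) or factor < 1:
        raise ValueError(f"factor must be an integer >= 1, got {factor!r}")
    if factor == 1:
        return LabelVolume(data=vol.data.copy(), affine=vol.affine.copy())
    data = vol.data
    for axis in range(3):
        data = np.repeat(data, factor, axis=axis)
    R = vol.affine[:3, :3] / factor
    # new voxel j has center at old index (j + 0.5)/factor - 0.5
    t = vol.affine[:3, 3] + vol.affine[:3, :3] @ np.full(3, (1 - factor) / (2 * factor))
    affine = np.eye(4)
    affine[:3, :3] = R
    affine[:3, 3] = t
    return LabelVolume(data=data, affine=affine)


def validate_aqueduct_connectivity(vol: LabelVolume) -> None:
    """Check that CA voxels form a single 26-connected component."""
    from scipy import ndimage

    mask = vol.mask(LABEL_AQUEDUCT)
    if not mask.any():
        raise ValueError("no aqueduct (label 2) voxels present")
    _, n = ndimage.label(mask, structure=np.ones((3, 3, 3), dtype=int))
    if n != 1:
        raise ValueError(f"aqueduct label has {n} 26-connected components, expected 1")
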