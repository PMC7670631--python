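# tectum

Level-set depth mapping and morphometry of the human dorsal midbrain.

The superior and inferior colliculi are small, laminated nuclei on the
dorsal surface of the midbrain (the tectum). Their layers run between
the superficial brainstem/CSF surface and, in depth, the periaqueductal
gray (PAG) that surrounds the cerebral aqueduct (CA). Probing that
laminar organization with structural or functional MRI needs a depth
coordinate adapted to the folded 3D geometry — plain nearest-surface
Euclidean depth oversamples deep tissue under convex hillocks and
undersamples it in the grooves between them.

`tectum` implements a two-surface algebraic level-set depth for this
anatomy. Given a brainstem segmentation (outer surface `S1`) and an
aqueduct segmentation (inner surface `S2`), it computes signed distances
`d1` and `d2` to both surfaces and the normalized depth

```
(1 - w) d1 + w d2 = 0    =>    w = d1 / (d1 - d2)
```

with `w = 0` on `S1` and `w = 1` on `S2`. On top of `w` the package
provides:

- **streamlines** of the depth gradient from every surface vertex, whose
  arclength is a physical tissue depth that plateaus at the aqueduct;
- **depth-averaging kernels** (streamline bundles, or straight cylinders
  for comparison) that pool any scalar volume — e.g. an fMRI statistic
  map — into binned depth profiles with bootstrap confidence intervals;
- **PAG boundary estimation**: gray-matter probability profiled against
  distance from the aqueduct, a spatial-uncertainty statistic
  `U = (sigma_P / P) / |dP/d d2|` minimized across subjects to pick the
  probability threshold, skeletonization of the aqueduct into a
  centerline, per-slice elliptical fits of the thresholded boundary
  (left-right semi-axis `a`, dorsal-ventral `b`, aspect ratio
  `eps = b/a`), and reconstruction of the fitted stack into a smooth 3D
  surface;
- **collicular thickness** from `S1` to the PAG under three metrics
  (Euclidean along the surface normal, streamline path length,
  normalized `w`), with automatic localization of the four collicular
  peaks and the two intercollicular sulci and Gaussian surface smoothing
  (1 mm FWHM) of the reported values;
- **synthetic phantoms** (concentric/eccentric spheres, a bumped
  midbrain-like tube) with analytic ground truth, so every stage is
  testable without subject data.

Inputs and outputs are NIfTI volumes with affines (via nibabel) and
PLY/OBJ meshes (via trimesh). See `docs/methods.md` for the numerical
details and design choices.

## Worked example

```python
import numpy as np
from tectum.phantom import PhantomSpec, make_concentric_spheres
from tectum.pipeline import depth_maps

# shell "brainstem" of radius 10 mm around a 3 mm "aqueduct", 0.7 mm voxels
spec = PhantomSpec(R1=10, R2=3, voxel=0.7, margin_voxels=8)
labels, truth = make_concentric_spheres(spec)

dm = depth_maps(labels)           # surfaces, d1/d2, w, gradient, streamlines
print(dm.qc.to_string(index=False))

r = np.linalg.norm(labels.grid_world_coordinates(), axis=-1)
interior = (r > 3.7) & (r < 9.3) & dm.w.valid
err = np.abs(dm.w.data - truth["w"](r))[interior]
print(f"max |w - (R1-r)/(R1-R2)| = {np.nanmax(err):.3f}")

depths = np.array([s.ca_crossing()[1] for s in dm.streamlines if s.complete])
print(f"path depth at the aqueduct: {depths.mean():.2f} mm (analytic 7.00)")
```

prints

```
  status  count  fraction
complete   3846       1.0
max |w - (R1-r)/(R1-R2)| = 0.024
path depth at the aqueduct: 7.01 mm (analytic 7.00)
```

i.e. every vertex's streamline reaches the aqueduct, the computed depth
coordinate matches the closed form for this geometry to ~0.02, and the
integrated path depth recovers the 7 mm shell thickness.

A command-line interface wraps the common steps:

```
tectum phantom concentric_spheres -o phantom/
tectum surface phantom/labels.nii.gz --label 1 --label 2 -o S1.ply
tectum depth --s1 S1.ply --s2 S2.ply --labels phantom/labels.nii.gz -o w.nii.gz
tectum trace --w w.nii.gz --s1 S1.ply -o streamlines/
```

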