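# Methods

`tectum` measures laminar depth and tissue thickness in the dorsal
midbrain between two reference surfaces: the superficial brainstem/CSF
interface **S1** and the cerebral aqueduct **S2**. This note documents the
model, the numerical choices and their rationale, what the synthetic
phantoms do and do not establish, and known limitations.

## The level-set depth model

Both reference surfaces are triangulated isosurfaces of binary
segmentations, refined by a volume-preserving smoothing. For every voxel
two signed Euclidean distances are computed to the nearest surface
triangle: `d1` (to S1) and `d2` (to S2), positive inside the region each
surface encloses. The normalized depth coordinate solves the algebraic
level-set relation

```
(1 - w) d1 + w d2 = 0        =>        w = d1 / (d1 - d2)
```

so `w = 0` on S1, `w = 1` on S2, `w < 0` outside the brainstem and
`w > 1` inside the aqueduct. Unlike single-surface Euclidean depth, `w`
is normalized to the local tissue span, and its isosurfaces morph
smoothly from the folded collicular surface into the aqueduct.

Treating `w` as a pseudopotential, streamlines of its gradient are traced
from every S1 vertex (fixed 0.25-voxel steps, trilinear gradient
interpolation), positive toward the aqueduct up to `w = 1.5` and negative
outward to `w = -1`. Arclength along a streamline is the *level-set
physical depth*; it plateaus at the aqueduct. Three safeguards terminate
pathological trajectories: a per-step direction change above 80 deg,
spatial progress below 0.05 voxels per iteration, and iteration caps
(64 positive / 32 negative steps by default). A streamline is *complete*
once it has reached `w >= 1`. The default caps suit midbrain-sized
anatomy (~8 mm tissue span at 0.7 mm voxels); the pipeline helper
(`tectum.pipeline.depth_maps`) sizes the positive cap to the tissue span
of the volume at hand, since a 16 mm phantom shell cannot be traversed in
64 quarter-voxel steps.

## Depth kernels and profiles

A depth-averaging kernel associates an S1 vertex with deeper tissue:
either the union of voxelized streamlines whose origins lie within a
manifold (geodesic) radius — 0.7 mm by default — of the vertex, or, for
comparison with the straight-line scheme, a cylinder extruded from the
same manifold disk along its mean normal. Scalar volumes are pooled over
kernel voxels into sliding depth bins (centers every 0.1 mm, 1.2 mm
width, span -0.5 to 3.5 mm by default) under any of four depth metrics
(Euclidean-from-S1, level-set path, normalized w, Euclidean-from-S2).
Across-run confidence intervals use a percentile bootstrap (runs resampled
with replacement, 2000 draws, 68% central interval, seeded generator);
the per-draw profile peak gives the peak-depth distribution.

## PAG boundary estimation

Gray-matter probability `P` is profiled against distance from the
aqueduct (`-d2`, binned at 0.05 mm). For a boundary whose position varies
across subjects, the positional uncertainty of an iso-probability contour
is

```
U = (sigma_P / P) * |dP/dd2|^(-1)      [mm]
```

where `sigma_P` is the across-subject SD of `P` at each distance. The
inverse-derivative form is fixed by dimensional analysis (U is a length);
the product form is available behind `mode="product"`. Each subject's
binned profile is moving-average smoothed (9 bins = 0.45 mm) *before*
the mean, SD and the five-point-stencil derivative are taken, so
numerator and denominator describe the same smeared profile and
voxel-composition jitter in the fine bins cancels in the ratio. U is then
re-expressed as a function of probability by averaging into 0.04-wide P
bins, and the working threshold `P_thr` is the argmin of U over bins where
at least half the subjects contribute, ties broken toward higher P. For a
family of shape-preserving boundaries jittered by `sigma_c`, the delta
method gives `U ~ sigma_c / P`, so the optimum sits at the top of the
usable probability range — on the calibration phantom the package returns
`P_thr = 0.94`, closely matching the high-probability optimum this
construction is designed to find.

The aqueduct segmentation is upsampled x2 and thinned to a 3D skeleton;
the longest geodesic path through the skeleton, smoothed with a 5-point
moving average, is the CA axis. (The thinning in scikit-image is
axis-order sensitive and can fully erode a symmetric tube in some
orientations; the implementation runs all six axis permutations and keeps
the richest skeleton.) In each plane normal to the axis the probability
volume is resampled on a 0.2 mm grid, the iso-contour at `P_thr` is
extracted by marching squares, the outermost closed contour enclosing the
axis is kept, and an origin-centered ellipse — left-right semi-axis `a`,
dorsal-ventral semi-axis `b`, aspect ratio `eps = b/a`, plus an in-plane
rotation — is fit by least squares on the radial residual. The fitted
ellipses are flood-filled back into a voxel segmentation, surfaced and
refined into `S_ellipse`, and compared with the iso-probability surface
`S_PAG` by symmetric per-vertex nearest-surface separation (mean, max,
fraction above 2 mm).

## Collicular landmarks and thickness

The collicular patch S_1A maps colliculus-labelled voxels to S1 by
nearest-neighbor association and expands the vertex set by 2 mm of
manifold distance. A quasi-sagittal plane (area-weighted total-least-
squares fit through the S2 vertices) separates left from right; an axial
plane at the midpoint of the 0.5-mm axial bin with the most negative mean
curvature (the transverse intercollicular groove) separates SC from IC.
In each quadrant a base plane is fit through the positive-curvature
vertices (oriented outward) and the peak is the vertex with maximum
distance from it on the convex side; peaks are deliberately defined by
straight-line distance so the landmark does not presuppose the streamline
machinery being evaluated. Each intercollicular sulcus is the S1 vertex
nearest the intersection of the left-right peak line with the sagittal
plane, required to lie within 0.25 mm of that plane.

Thickness from S1 to a PAG surface is measured three ways: the
first-intersection distance of the inward-normal ray (Euclidean); the
path distance along the vertex's streamline to its first PAG entry
(streamline); and `w` interpolated at that entry point (normalized).
Reported landmark values are smoothed with a Gaussian manifold-distance
kernel (2 mm diameter, 1 mm FWHM, `sigma = FWHM / (2 sqrt(2 ln 2))`),
`T = sum(A_n t_n) / sum(A_n)` with `A_n = exp(-d_m^2 / 2 sigma^2)`.

On concentric geometry the streamline metric cannot undercut the
Euclidean one (both measure the same radial chord), and the suite asserts
this ordering there. On eccentric geometry the two metrics terminate at
*different* PAG points, and either can be larger — the streamline path
can be a few percent shorter than an obliquely incident normal ray. This
is a property of the definitions, not an error.

## Numerical choices

- **Isosurfacing and refinement.** Marching cubes on the signed distance
  transform of the label mask, then umbrella (curvature-flow style)
  smoothing with an exact per-iteration volume rescale about the
  centroid; 5 iterations by default. Volume drift is floating-point only.
  The cited variational refinement scheme is not specified in detail
  anywhere reproducible, so this volume-preserving substitute with
  testable guarantees is used instead.
- **Exact distance queries.** Point-to-triangle distance is the scalar
  region-based closest-point algorithm; a uniform spatial grid over
  triangles with a provable ring-termination bound prunes candidates, so
  results equal an exhaustive scan (asserted to 1e-6 mm in the suite).
  numba compiles the inner loops.
- **Gradient estimation.** Five-point central-difference stencils per
  axis, mapped to world coordinates through the affine. The depth field
  is pre-smoothed with a 1.5-voxel Gaussian: the smoothing leaves
  derivatives of linear and quadratic fields unchanged and suppresses the
  voxel-scale ripple that binary segmentations imprint on the distance
  fields. Without it, ripple-induced tangential gradient components
  deflect streamlines by several tenths of a millimetre over deep paths.
- **Surface normals for tracing and normal-ray thickness** are sampled
  from the (smoothed) level-set gradient at the vertices rather than
  averaged from mesh faces: on marching-cubes meshes face normals carry
  2-12 degrees of angular noise, while field normals are accurate to
  well under a degree. Mesh normals remain the fallback where the
  gradient is invalid.
- **Streamline -> voxel association** rounds sample coordinates to the
  nearest voxel; the level-set depth volume averages path-depth samples
  per voxel and fills unsampled masked voxels from the nearest sampled
  voxel (scattered-data interpolation degenerates at the voxel scale
  here, so the nearest-sample fallback is the default).
- **Geodesics** use shortest paths on the mesh edge graph augmented with
  two-ring Euclidean chords, cutting the metric overestimation from ~6%
  to ~2%; at the 0.7-2 mm radii used the residual error is far below the
  voxel size.
- **Degenerate inputs.** Voxels with `|d1 - d2| < 1e-6 mm` are masked
  invalid; zero-area triangles, empty label regions, regions touching the
  grid boundary, disconnected aqueducts and sub-minimal quadrants raise
  errors rather than propagate.

## What the phantoms show — and what they do not

The generators produce binary label volumes, logistic-edge probability
maps and depth-localized Gaussian activations with analytic ground truth:

- concentric spheres (R1 = 20 mm, R2 = 4 mm, 0.7 mm voxels by default),
  where `w(r)` and path depth are closed-form;
- eccentric spheres (inner ball offset 2 mm), where line-sphere
  intersections and an analytic-gradient ray tracer provide thickness
  oracles;
- a midbrain-like slab with four Gaussian hillocks in two pairs, a
  transverse groove, and an elliptical aqueduct tube (dorsal-ventral
  radius larger than left-right, as in anatomy, which also conditions the
  sagittal-plane fit).

Default geometric parameters are the anatomy-motivated scales above;
probability-map calibration uses a boundary 6 mm outside the aqueduct
with a 1.2 mm logistic edge and 0.3 mm across-subject jitter, placing the
delta-method regime (`sigma_c` well below the edge scale) that the
`U * P = const` prediction assumes. Ellipse recovery uses 0.35 mm voxels
(the high-resolution regime) with semi-axes 1.5-4 mm and 0.1 mm radial
boundary noise.

Phantoms exercise every pipeline stage against ground truth, but they are
smooth, noise-free (except where noise is planted), perfectly segmented
geometries. Passing tests demonstrate correctness of the numerics, not
robustness to real segmentation errors, partial-volume effects, B1
inhomogeneity or motion. Subject-level results from the original study
population (group thickness tables, the 0.96 probability threshold, PAG
separation statistics) depend on scans that are not publicly deposited
and are not reproduced here.

## Known limitations

- Deviation from the origin-normal line (delta-d) is asserted sub-voxel
  over the 0-3.5 mm span used for depth profiling. At depths beyond
  ~12 mm on the 16 mm phantom shell it grows to ~0.3-0.6 voxels: any
  normal direction estimated from a binary segmentation carries ~0.5 deg
  of angular noise, which a 16 mm lever arm amplifies past 0.1 voxel.
  The deep values are computed and reported by `scripts/acceptance.py`.
- The edge-graph geodesic remains a ~2% overestimate; kernel radii are
  effectively a hair tighter than nominal.
- Ellipse fits assume a star-shaped outer contour about the CA axis;
  strongly non-convex PAG cross-sections (dimples) are smoothed over, as
  intended for boundary reconstruction, and rotation is reported but not
  used to reorient the axes.
- The w field is validated within the band `-1 <= w <= 1.5` the method
  uses; values outside that band (far exterior, non-convex pockets) are
  computed but unvalidated.
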