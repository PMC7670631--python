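"""End-to-end convenience pipeline from a label volume to depth products.

Wires the standard stages together with consistent choices: surfaces from
the tissue and aqueduct labels (refined), both signed distance fields on a
shared evaluation region (the outer surface's padded bounding box, so the
level-set ratio and the negative streamline segments are defined outside
the tissue as well), the normalized depth w, its gradient, and streamlines
from every S1 vertex.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import trimesh

from tectum.depth_field import (
    NormalizedDepthField,
    SignedDistanceField,
    _evaluation_mask,
    normalized_depth,
    signed_distance_field,
)
from tectum.streamline import (
    GradientField,
    Streamline,
    TraceParams,
    field_normals,
    gradient_field,
    trace_all,
)
from tectum.surface_model import extract_isosurface, refine_surface
from tectum.volume_io import LABEL_AQUEDUCT, LabelVolume


@dataclass
class DepthMaps:
    """Products of the depth-mapping pipeline."""

    s1: trimesh.Trimesh
    s2: trimesh.Trimesh
    d1: SignedDistanceField
    d2: SignedDistanceField
    w: NormalizedDepthField
    grad: GradientField
    normals: np.ndarray | None = None  # outward S1 vertex normals (field-based)
    streamlines: list[Streamline] | None = None
    qc: pd.DataFrame | None = None


def depth_maps(
    labels: LabelVolume,
    tissue_labels=(1, 2, 3),
    refine_iterations: int = 5,
    margin_voxels: int = 8,
    trace: bool = True,
    trace_params: TraceParams | None = None,
    trace_vertices: np.ndarray | None = None,
) -> DepthMaps:
    """Run segmentation -> surfaces -> d1/d2 -> w -> gradient -> streamlines.

    ``tissue_labels`` are the labels enclosed by the outer surface S1
    (tissue plus aqueduct); the aqueduct label alone bounds S2.  The
    iteration cap for tracing defaults to enough steps to traverse the
    tissue span of the volume at the configured step size.
    """
    s1 = refine_surface(extract_isosurface(labels, tissue_labels), refine_iterations)
    s2 = refine_surface(
        extract_isosurface(labels, LABEL_AQUEDUCT), refine_iterations
    )
    s1.metadata["role"] = "S1"
    s2.metadata["role"] = "S2"
    inside1 = np.isin(labels.data, np.asarray(tissue_labels, dtype=int))
    inside2 = labels.mask(LABEL_AQUEDUCT)
    shared = _evaluation_mask(labels, s1, margin_voxels)
    d1 = signed_distance_field(
        s1, labels, inside1, reference="S1", eval_mask=shared
    )
    d2 = signed_distance_field(
        s2, labels, inside2, reference="S2", eval_mask=shared
    )
    w = normalized_depth(d1, d2)
    grad = gradient_field(w)
    normals = field_normals(s1, grad, w)
    out = DepthMaps(s1=s1, s2=s2, d1=d1, d2=d2, w=w, grad=grad, normals=normals)
    if trace:
        if trace_params is None:
            # size the iteration cap to the tissue span so tracing is not
            # artificially truncated on large phantoms
            span = float(np.nanmax(np.abs(d1.data[np.isfinite(d1.data)])))
            step_mm = 0.25 * labels.mean_voxel_edge
            cap = int(np.ceil(1.6 * span / step_mm))
            trace_params = TraceParams(max_iter_pos=max(cap, 64))
        out.streamlines, out.qc = trace_all(
            s1, grad, w, trace_params, vertices=trace_vertices, normals=normals
        )
    return out
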