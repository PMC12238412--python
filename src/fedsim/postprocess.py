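"""Label-map post-processing operators for segmentation predictions.

These are the mask-level clean-up steps commonly applied to multi-class
tumor segmentations before evaluation:

* :func:`fill_tc` — fill holes enclosed by the tumor core, slice by
  slice along each anatomical orientation, relabeling them to NCR
  (significant tumors rarely contain voids of healthy tissue).
* :func:`small_et_to_ncr` — demote an implausibly small enhancing-tumor
  prediction to necrotic core.
* :func:`drop_small_components` — remove small connected components of
  a region mask.

All operators take and return :class:`~fedsim.metrics.LabelMap` objects
and never introduce label values outside {0, 1, 2, 4}.
"""

from __future__ import annotations

import numpy as np
from scipy import ndimage

from .metrics import REGION_LABELS, LabelMap

__all__ = ["fill_tc", "small_et_to_ncr", "drop_small_components"]

# Orientation order for slice-wise processing of 3-D volumes: slicing
# along the last axis first (axial for x,y,z-ordered volumes), then the
# middle (coronal) and first (sagittal) axes.
_ORIENTATION_AXES_3D = (2, 1, 0)


def _fill_slice_pass(values: np.ndarray, axis: int) -> np.ndarray:
    """One slice-wise hole-filling pass perpendicular to ``axis``.

    Within each 2-D slice, non-TC pixels in regions fully enclosed by
    TC pixels (4-connectivity of the background) are relabeled to NCR
    (label 1).  Pixels already labeled 1 or 4 are never modified.
    """
    out = values.copy()
    moved = np.moveaxis(out, axis, 0)
    for idx in range(moved.shape[0]):
        plane = moved[idx]
        tc = np.isin(plane, REGION_LABELS["TC"])
        if not tc.any():
            continue
        # binary_fill_holes with the default cross-shaped structure uses
        # 4-connectivity for the background, i.e. a region counts as a
        # hole only if it cannot reach the slice border through
        # face-adjacent non-TC pixels.
        filled = ndimage.binary_fill_holes(tc)
        plane[filled & ~tc] = 1
    return out


def fill_tc(labels: LabelMap, until_convergence: bool = False) -> LabelMap:
    """Relabel voxels enclosed by tumor core (TC = labels {1, 4}) to NCR.

    The filling is applied slice by slice, one pass per orientation in
    the order axial → coronal → sagittal for 3-D volumes; a 2-D map is
    treated as a single axial slice (one pass).  Enclosure uses
    4-connectivity of the non-TC background within each slice, so a
    region touching the slice border is never filled.  Edema voxels
    enclosed by core are relabeled along with background; NCR and ET
    voxels are never changed.

    With ``until_convergence=True`` the orientation cycle is repeated
    until the map reaches a fixed point instead of running exactly once.
    """
    values = labels.values
    if values.ndim == 2:
        axes: tuple[int, ...] = (0,)
        values = values[None, ...]
        squeeze = True
    elif values.ndim == 3:
        axes = _ORIENTATION_AXES_3D
        squeeze = False
    else:
        raise ValueError("fill_tc expects a 2-D or 3-D label map")

    while True:
        before = values
        for axis in axes:
            values = _fill_slice_pass(values, axis)
        if not until_convergence or np.array_equal(values, before):
            break
    if squeeze:
        values = values[0]
    return LabelMap(values=values, spacing=labels.spacing)


def small_et_to_ncr(
    labels: LabelMap,
    min_voxels: int,
    per_component: bool = False,
    connectivity: int = 1,
) -> LabelMap:
    """Relabel enhancing tumor to NCR when its volume is implausibly small.

    If the total ET voxel count is strictly below ``min_voxels``, all ET
    voxels become NCR (label 1); with ``per_component=True`` the strict
    threshold is applied to each connected ET component instead
    (``connectivity`` in the scipy sense: 1 = faces only).
    ``min_voxels=0`` is the identity.
    """
    if min_voxels < 0:
        raise ValueError("min_voxels must be >= 0")
    values = labels.values.copy()
    et = values == 4
    if not et.any():
        return LabelMap(values=values, spacing=labels.spacing)
    if per_component:
        structure = ndimage.generate_binary_structure(values.ndim, connectivity)
        comp, n_comp = ndimage.label(et, structure=structure)
        sizes = ndimage.sum_labels(et, comp, index=np.arange(1, n_comp + 1))
        for i, size in enumerate(sizes, start=1):
            if size < min_voxels:
                values[comp == i] = 1
    elif int(et.sum()) < min_voxels:
        values[et] = 1
    return LabelMap(values=values, spacing=labels.spacing)


def drop_small_components(
    labels: LabelMap,
    region: str,
    min_voxels: int,
    connectivity: int = 1,
) -> LabelMap:
    """Set connected components of a region mask smaller than a threshold
    to background.

    Components of the ``region`` mask (WT, TC or ET) with strictly
    fewer than ``min_voxels`` voxels are erased to label 0.
    ``connectivity`` follows scipy's convention (1 = face connectivity,
    the default for 3-D drops).  ``min_voxels <= 1`` is the identity.
    """
    if region not in REGION_LABELS:
        raise ValueError(f"unknown region {region!r}")
    values = labels.values.copy()
    mask = np.isin(values, REGION_LABELS[region])
    if not mask.any():
        return LabelMap(values=values, spacing=labels.spacing)
    structure = ndimage.generate_binary_structure(values.ndim, connectivity)
    comp, n_comp = ndimage.label(mask, structure=structure)
    sizes = ndimage.sum_labels(mask, comp, index=np.arange(1, n_comp + 1))
    for i, size in enumerate(sizes, start=1):
        if size < min_voxels:
            values[comp == i] = 0
    return LabelMap(values=values, spacing=labels.spacing)
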