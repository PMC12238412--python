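"""Segmentation metrics and the convergence score.

Evaluation follows the BraTS convention: a label map contains the values
0 (background), 1 (necrotic core, NCR), 2 (peritumoral edema, ED) and
4 (enhancing tumor, ET).  Quality is assessed on three nested regions —

* whole tumor   WT = labels in {1, 2, 4}
* tumor core    TC = labels in {1, 4}
* enhancing     ET = label 4

— each scored with the Dice similarity coefficient (overlap, higher is
better) and the 95th-percentile symmetric boundary distance HD95 (lower
is better).  The convergence score summarizes a federated run as the
normalized area under the running-max validation-DSC-over-simulated-time
curve within a fixed time budget.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
from scipy import ndimage

__all__ = [
    "VALID_LABELS",
    "REGIONS",
    "REGION_LABELS",
    "HD95_EMPTY_SENTINEL",
    "LabelMap",
    "RegionMask",
    "ConvergenceCurve",
    "regions_from_labels",
    "region_mask",
    "dsc",
    "hd95",
    "boundary_mask",
    "mean_region_dsc",
    "convergence_score",
]

VALID_LABELS = frozenset({0, 1, 2, 4})

#: Region names in canonical reporting order.
REGIONS = ("WT", "TC", "ET")

#: Label sets whose union defines each region.
REGION_LABELS = {"WT": (1, 2, 4), "TC": (1, 4), "ET": (4,)}

#: Distance (in spacing units) reported when exactly one mask is empty and a
#: boundary distance is therefore undefined.  The default is the
#: image-diagonal penalty commonly used by the BraTS community for the
#: 240x240x155 grid; it is configurable per call and recorded alongside
#: results by the CLI.
HD95_EMPTY_SENTINEL = 373.13


def _check_labels(values: np.ndarray) -> None:
    bad = np.setdiff1d(np.unique(values), sorted(VALID_LABELS))
    if bad.size:
        raise ValueError(
            f"label map contains invalid values {bad.tolist()}; "
            f"expected a subset of {sorted(VALID_LABELS)}"
        )


@dataclass(frozen=True)
class LabelMap:
    """Integer voxel grid with BraTS labels {0, 1, 2, 4}.

    Parameters
    ----------
    values
        Integer array of any dimensionality (2-D slices and 3-D volumes
        are both supported).
    spacing
        Physical voxel size along each axis, in arbitrary distance units
        (defaults to isotropic 1.0).
    """

    values: np.ndarray
    spacing: tuple[float, ...] = None  # type: ignore[assignment]

    def __post_init__(self) -> None:
        values = np.asarray(self.values)
        if not np.issubdtype(values.dtype, np.integer):
            raise TypeError("label map values must be integers")
        _check_labels(values)
        spacing = self.spacing
        if spacing is None:
            spacing = (1.0,) * values.ndim
        spacing = tuple(float(s) for s in spacing)
        if len(spacing) != values.ndim:
            raise ValueError("spacing length must match number of axes")
        if any(s <= 0 for s in spacing):
            raise ValueError("spacing must be strictly positive")
        object.__setattr__(self, "values", values)
        object.__setattr__(self, "spacing", spacing)

    @property
    def shape(self) -> tuple[int, ...]:
        return self.values.shape


@dataclass(frozen=True)
class RegionMask:
    """Boolean mask of one tumor region (WT, TC or ET)."""

    region: str
    mask: np.ndarray
    spacing: tuple[float, ...]

    def __post_init__(self) -> None:
        if self.region not in REGIONS:
            raise ValueError(f"unknown region {self.region!r}; expected one of {REGIONS}")
        object.__setattr__(self, "mask", np.asarray(self.mask, dtype=bool))
        object.__setattr__(self, "spacing", tuple(float(s) for s in self.spacing))

    @property
    def n_voxels(self) -> int:
        return int(self.mask.sum())


def region_mask(labels: LabelMap, region: str) -> RegionMask:
    """Boolean mask of ``region`` derived from a label map."""
    if region not in REGION_LABELS:
        raise ValueError(f"unknown region {region!r}; expected one of {REGIONS}")
    mask = np.isin(labels.values, REGION_LABELS[region])
    return RegionMask(region=region, mask=mask, spacing=labels.spacing)


def regions_from_labels(labels: LabelMap) -> dict[str, RegionMask]:
    """Map a label map to its three nested evaluation regions.

    Returns a dict keyed by region name; by construction
    ``ET ⊆ TC ⊆ WT``.
    """
    return {region: region_mask(labels, region) for region in REGIONS}


def _check_compatible(pred: RegionMask, ref: RegionMask) -> None:
    if pred.mask.shape != ref.mask.shape:
        raise ValueError(
            f"mask shape mismatch: {pred.mask.shape} vs {ref.mask.shape}"
        )
    if pred.spacing != ref.spacing:
        raise ValueError(f"spacing mismatch: {pred.spacing} vs {ref.spacing}")


def dsc(pred: RegionMask, ref: RegionMask) -> float:
    """Dice similarity coefficient ``2|Y ∩ Ŷ| / (|Y| + |Ŷ|)``.

    Ranges from 0 (no overlap) to 1 (identical masks).  Conventions for
    degenerate inputs: both masks empty → 1.0 (perfect agreement on
    absence); exactly one empty → 0.0.
    """
    _check_compatible(pred, ref)
    n_pred = pred.n_voxels
    n_ref = ref.n_voxels
    if n_pred == 0 and n_ref == 0:
        return 1.0
    if n_pred == 0 or n_ref == 0:
        return 0.0
    intersection = int(np.logical_and(pred.mask, ref.mask).sum())
    return 2.0 * intersection / (n_pred + n_ref)


def boundary_mask(mask: np.ndarray) -> np.ndarray:
    """Boundary voxels of a binary mask.

    A mask voxel is on the boundary if at least one face-adjacent
    neighbor is outside the mask; voxels on the array edge count as
    boundary (the exterior is treated as background).
    """
    mask = np.asarray(mask, dtype=bool)
    structure = ndimage.generate_binary_structure(mask.ndim, 1)
    eroded = ndimage.binary_erosion(mask, structure=structure, border_value=0)
    return mask & ~eroded


def hd95(
    pred: RegionMask,
    ref: RegionMask,
    empty_value: float = HD95_EMPTY_SENTINEL,
) -> float:
    """95th-percentile symmetric boundary (Hausdorff) distance.

    Boundary voxel sets are extracted from both masks (face
    connectivity); for each direction the Euclidean distances from one
    boundary to the nearest voxel of the other are collected and the
    maximum of the two 95th percentiles (linear-interpolation
    definition) is returned, in physical spacing units.  Lower is
    better; identical masks score 0.

    If exactly one mask is empty the distance is undefined and
    ``empty_value`` is returned; if both are empty the score is 0.0
    (agreement on absence).
    """
    _check_compatible(pred, ref)
    if pred.n_voxels == 0 and ref.n_voxels == 0:
        return 0.0
    if pred.n_voxels == 0 or ref.n_voxels == 0:
        return float(empty_value)
    b_pred = boundary_mask(pred.mask)
    b_ref = boundary_mask(ref.mask)
    spacing = pred.spacing
    # Distance transform of the complement gives, at every voxel, the
    # exact Euclidean distance to the nearest boundary voxel.
    dt_ref = ndimage.distance_transform_edt(~b_ref, sampling=spacing)
    dt_pred = ndimage.distance_transform_edt(~b_pred, sampling=spacing)
    d_pred_to_ref = dt_ref[b_pred]
    d_ref_to_pred = dt_pred[b_ref]
    return float(
        max(
            np.percentile(d_pred_to_ref, 95),
            np.percentile(d_ref_to_pred, 95),
        )
    )


def mean_region_dsc(pred: LabelMap, ref: LabelMap) -> float:
    """Mean DSC over the three tumor regions of one case."""
    pred_regions = regions_from_labels(pred)
    ref_regions = regions_from_labels(ref)
    return float(
        np.mean([dsc(pred_regions[r], ref_regions[r]) for r in REGIONS])
    )


@dataclass
class ConvergenceCurve:
    """Validation-DSC-over-simulated-time curve of one federated run.

    ``points`` is an ordered list of ``(time, dsc)`` pairs where ``time``
    is the cumulative simulated time (hours) at which the corresponding
    global model finished its round, starting with the initial model at
    t = 0.  ``budget`` is the total simulated time allowed (default one
    week = 168 h).
    """

    points: list[tuple[float, float]] = field(default_factory=list)
    budget: float = 168.0

    def append(self, time: float, value: float) -> None:
        if self.points and time <= self.points[-1][0]:
            raise ValueError("curve times must be strictly increasing")
        if not 0.0 <= value <= 1.0:
            raise ValueError("DSC values must lie in [0, 1]")
        self.points.append((float(time), float(value)))


def convergence_score(curve: ConvergenceCurve) -> float:
    """Normalized area under the projected (running-max) DSC curve.

    The validation DSC may drop at later rounds, but since the
    best-validation model is kept as the final model such drops are not
    penalized: the curve is first projected to its running maximum
    ``DSC_proj(t) = max_{t' ≤ t} DSC(t')``.  The curve is treated as a
    step function (the DSC is only observed at round boundaries), held
    at its last projected value until the budget and at 0 before the
    first point.  Points beyond the budget are discarded — a terminating
    round that exceeds the budget earns no credit.  The step-function
    area is divided by the budget, giving a score in [0, 1].
    """
    if curve.budget <= 0:
        raise ValueError("budget must be positive")
    points = [(t, v) for t, v in curve.points if t <= curve.budget]
    if not points:
        if not curve.points:
            raise ValueError("convergence curve has no points")
        return 0.0
    times = np.asarray([p[0] for p in points], dtype=float)
    values = np.asarray([p[1] for p in points], dtype=float)
    if np.any(np.diff(times) <= 0):
        raise ValueError("curve times must be strictly increasing")
    projected = np.maximum.accumulate(values)
    edges = np.append(times, curve.budget)
    widths = np.diff(edges)
    area = float(np.sum(projected * widths))
    return area / curve.budget
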