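"""Synthetic multi-institution segmentation federations.

Real multi-site tumor-segmentation federations exhibit three statistical
features that matter for benchmarking aggregation algorithms: heavily
skewed per-site case counts, site-specific acquisition shifts (intensity
scale/offset and noise level), and nested tumor sub-regions (an edema
shell around a core split into necrotic tissue and an enhancing blob).
This module generates small image phantoms with exactly that structure,
at desk scale (default 32x32 2-D grids; small 3-D grids work too), so
whole federated experiments finish in minutes.

Each case carries a 4-channel image emulating the structural MRI
sequences (channel 0: T1, 1: T1-Gd, 2: T2, 3: FLAIR) and a label map
with the BraTS convention {0, 1 (NCR), 2 (ED), 4 (ET)}.  Tissue classes
have distinct per-channel intensity signatures — notably the contrast
channel (T1-Gd) is elevated only inside ET — so that a small model can
learn the task from intensities alone.

Also implemented here are the challenge-style partitioning schemes: a
"geographic" federation is a list of generated sites; the "artificial"
refinement splits the largest sites into equal thirds after sorting
cases by whole-tumor size, producing clients whose tumor-size
distributions differ systematically.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Literal, Sequence

import numpy as np

from .metrics import LabelMap

__all__ = [
    "SitePhantomSpec",
    "Case",
    "ClientDataset",
    "Federation",
    "generate_site",
    "make_federation",
    "partition_artificial",
    "validation_split_size",
    "export_cases_nifti",
]

#: Per-class mean intensity signature, rows indexed by channel
#: (T1, T1-Gd, T2, FLAIR), columns by tissue (background, NCR, ED, ET).
_CLASS_INTENSITY = np.array(
    [
        # bg    NCR   ED    ET
        [0.20, 0.10, 0.30, 0.45],  # T1
        [0.20, 0.25, 0.30, 0.90],  # T1-Gd: elevated only inside ET
        [0.20, 0.55, 0.70, 0.50],  # T2
        [0.20, 0.50, 0.85, 0.55],  # FLAIR
    ]
)
_LABEL_TO_COLUMN = {0: 0, 1: 1, 2: 2, 4: 3}


@dataclass(frozen=True)
class SitePhantomSpec:
    """Generation parameters of one simulated institution.

    ``intensity_scale`` / ``intensity_offset`` apply a per-channel
    affine shift to every image of the site (the site's "scanner"),
    ``noise_sigma`` sets the additive Gaussian noise level, and the
    tumor ranges control lesion geometry: radii in voxels and the
    fraction of the tumor core occupied by enhancing tumor.
    """

    site_id: str
    n_cases: int
    intensity_scale: tuple[float, float, float, float] = (1.0, 1.0, 1.0, 1.0)
    intensity_offset: tuple[float, float, float, float] = (0.0, 0.0, 0.0, 0.0)
    noise_sigma: float = 0.05
    tumor_radius_range: tuple[float, float] = (5.0, 10.0)
    et_fraction_range: tuple[float, float] = (0.2, 0.5)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_cases < 1:
            raise ValueError("n_cases must be >= 1")
        if any(s <= 0 for s in self.intensity_scale):
            raise ValueError("intensity_scale entries must be positive")
        if self.noise_sigma < 0:
            raise ValueError("noise_sigma must be >= 0")
        lo, hi = self.tumor_radius_range
        if not 0 < lo <= hi:
            raise ValueError("tumor_radius_range must satisfy 0 < min <= max")
        flo, fhi = self.et_fraction_range
        if not (0 < flo <= fhi < 1):
            raise ValueError("et_fraction_range bounds must lie in (0, 1)")


@dataclass(frozen=True)
class Case:
    """One simulated patient: 4-channel image plus reference labels."""

    image: np.ndarray  # shape (4, *grid)
    labels: LabelMap
    wt_size: int
    site_id: str
    case_id: str

    def __post_init__(self) -> None:
        wt = int(np.isin(self.labels.values, (1, 2, 4)).sum())
        if wt != self.wt_size:
            raise ValueError("wt_size does not match the label map")


@dataclass
class ClientDataset:
    """One institution's cases with a fixed train/validation split."""

    site_id: str
    cases: list[Case]
    train_indices: list[int]
    val_indices: list[int]

    def __post_init__(self) -> None:
        n = len(self.cases)
        if sorted(self.train_indices + self.val_indices) != list(range(n)):
            raise ValueError("train and validation indices must partition the cases")

    @property
    def n_cases(self) -> int:
        return len(self.cases)

    @property
    def n_train(self) -> int:
        return len(self.train_indices)

    @property
    def n_val(self) -> int:
        return len(self.val_indices)

    @property
    def train_cases(self) -> list[Case]:
        return [self.cases[i] for i in self.train_indices]

    @property
    def val_cases(self) -> list[Case]:
        return [self.cases[i] for i in self.val_indices]


@dataclass
class Federation:
    """A list of client datasets forming one simulated federation."""

    clients: list[ClientDataset]
    partitioning_id: str = "geographic"

    def __post_init__(self) -> None:
        ids = [c.site_id for c in self.clients]
        if len(set(ids)) != len(ids):
            raise ValueError("site_ids must be unique")

    @property
    def n_cases(self) -> int:
        return sum(c.n_cases for c in self.clients)

    @property
    def sizes(self) -> dict[str, int]:
        return {c.site_id: c.n_cases for c in self.clients}

    def client(self, site_id: str) -> ClientDataset:
        for c in self.clients:
            if c.site_id == site_id:
                return c
        raise KeyError(site_id)


def validation_split_size(n_cases: int, fraction: float = 0.2) -> int:
    """Number of validation cases: ``max(1, round(fraction * n))``.

    Rounding is half-up so a 10-case client gets exactly 2 validation
    cases and every client keeps at least one.
    """
    return max(1, int(np.floor(fraction * n_cases + 0.5)))


def _draw_lesion(
    grid: tuple[int, ...],
    rng: np.random.Generator,
    radius_range: tuple[float, float],
    et_fraction_range: tuple[float, float],
) -> np.ndarray:
    """Random nested-ellipsoid lesion on an empty grid.

    The whole tumor is a random ellipsoid; the tumor core is a
    concentric ellipsoid (the shell between them is edema).  Within the
    core, the enhancing tumor is the centre-most fraction of core
    voxels, so the realized ET/TC voxel ratio tracks the sampled
    fraction closely and ET is always a single connected central blob
    (giving hole-filling operators realistic inputs).
    """
    ndim = len(grid)
    radius = rng.uniform(*radius_range)
    # Mild per-axis anisotropy so lesions are ellipsoids, not spheres.
    axes = radius * rng.uniform(0.75, 1.25, size=ndim)
    margin = axes + 1.0
    lo = margin
    hi = np.asarray(grid) - 1 - margin
    if np.any(hi < lo):
        raise ValueError(
            "geometry too small for tumor_radius_range: a lesion of radius "
            f"{radius:.1f} cannot fit inside grid {grid}"
        )
    center = np.array([rng.uniform(l, h) for l, h in zip(lo, hi)])

    coords = np.indices(grid, dtype=float)
    # Normalized elliptical radius: <=1 inside the whole tumor.
    r2 = np.zeros(grid, dtype=float)
    for d in range(ndim):
        r2 += ((coords[d] - center[d]) / axes[d]) ** 2
    wt = r2 <= 1.0

    core_scale = rng.uniform(0.5, 0.8)  # edema shell thickness
    tc = r2 <= core_scale**2
    labels = np.zeros(grid, dtype=np.int16)
    labels[wt] = 2
    n_tc = int(tc.sum())
    if n_tc > 0:
        labels[tc] = 1
        et_fraction = rng.uniform(*et_fraction_range)
        n_et = int(np.floor(et_fraction * n_tc + 0.5))
        if n_et > 0:
            tc_idx = np.argwhere(tc)
            tc_r2 = r2[tc]
            order = np.argsort(tc_r2, kind="stable")
            chosen = tc_idx[order[:n_et]]
            labels[tuple(chosen.T)] = 4
    return labels


def _render_case(
    labels: np.ndarray,
    spec: SitePhantomSpec,
    rng: np.random.Generator,
) -> np.ndarray:
    """Render the 4-channel image for a label map with site effects."""
    grid = labels.shape
    image = np.empty((4,) + grid, dtype=np.float64)
    for label, col in _LABEL_TO_COLUMN.items():
        mask = labels == label
        if not mask.any():
            continue
        for ch in range(4):
            image[ch][mask] = _CLASS_INTENSITY[ch, col]
    noise = rng.normal(0.0, spec.noise_sigma, size=image.shape)
    scale = np.asarray(spec.intensity_scale).reshape((4,) + (1,) * len(grid))
    offset = np.asarray(spec.intensity_offset).reshape((4,) + (1,) * len(grid))
    # Site effects: the affine scanner shift is applied after the noise
    # draw so two sites differing only in offset produce voxel-wise
    # identical images up to that exact offset (same seed).
    return (image + noise) * scale + offset


def generate_site(
    spec: SitePhantomSpec,
    geometry: tuple[int, ...] = (32, 32),
    val_fraction: float = 0.2,
) -> ClientDataset:
    """Generate one site's dataset of lesion phantoms.

    ``geometry`` is the 2-D or 3-D grid shape (all dims >= 16).  The
    generation is a pure function of (spec, geometry): the same spec
    produces bitwise-identical datasets.  A 20% validation split (at
    least one case) is drawn from the same seed.
    """
    geometry = tuple(int(g) for g in geometry)
    if len(geometry) not in (2, 3) or any(g < 16 for g in geometry):
        raise ValueError("geometry must be 2-D or 3-D with all dims >= 16")
    rng = np.random.default_rng(np.random.SeedSequence([int(spec.seed) % 2**31, 0xFE75]))
    cases = []
    for i in range(spec.n_cases):
        labels = _draw_lesion(
            geometry, rng, spec.tumor_radius_range, spec.et_fraction_range
        )
        image = _render_case(labels, spec, rng)
        cases.append(
            Case(
                image=image,
                labels=LabelMap(values=labels),
                wt_size=int((labels > 0).sum()),
                site_id=spec.site_id,
                case_id=f"{spec.site_id}-{i:04d}",
            )
        )
    n_val = validation_split_size(spec.n_cases, val_fraction)
    perm = rng.permutation(spec.n_cases)
    val_idx = sorted(int(i) for i in perm[:n_val])
    train_idx = sorted(int(i) for i in perm[n_val:])
    return ClientDataset(
        site_id=spec.site_id,
        cases=cases,
        train_indices=train_idx,
        val_indices=val_idx,
    )


def make_federation(
    specs: Sequence[SitePhantomSpec],
    size_law: Literal["poisson", "lognormal", "fixed"] = "fixed",
    rng_seed: int = 0,
    geometry: tuple[int, ...] = (32, 32),
    partitioning_id: str = "geographic",
) -> Federation:
    """Assemble a federation, optionally redrawing per-site case counts.

    With ``size_law="fixed"`` each spec's ``n_cases`` is used verbatim.
    ``"poisson"`` redraws each site's count from Poisson(spec.n_cases)
    — the canonical skewed-site-size model — and ``"lognormal"`` from a
    log-normal with median ``spec.n_cases`` (sigma = 0.5).  A site drawn
    with zero cases is redrawn until nonzero, so no client is ever
    empty.
    """
    if len(specs) < 2:
        raise ValueError("a federation needs at least 2 sites")
    rng = np.random.default_rng(np.random.SeedSequence([int(rng_seed) % 2**31, 0xFED]))
    clients = []
    for spec in specs:
        if size_law == "fixed":
            n = spec.n_cases
        elif size_law == "poisson":
            n = 0
            while n == 0:
                n = int(rng.poisson(spec.n_cases))
        elif size_law == "lognormal":
            n = 0
            while n == 0:
                n = int(np.floor(rng.lognormal(np.log(spec.n_cases), 0.5) + 0.5))
        else:
            raise ValueError(f"unknown size_law {size_law!r}")
        clients.append(generate_site(replace(spec, n_cases=n), geometry=geometry))
    return Federation(clients=clients, partitioning_id=partitioning_id)


def partition_artificial(
    fed: Federation,
    n_largest: int = 5,
    n_splits: int = 3,
) -> Federation:
    """Split the largest sites by whole-tumor size (artificial partitioning).

    Each of the ``n_largest`` biggest clients is split into ``n_splits``
    equally large parts (sizes differing by at most one) after sorting
    its cases by whole-tumor voxel count, ties broken by case index
    (stable sort).  Other clients pass through unchanged; the multiset
    of cases is preserved.  New site ids are ``"<parent>-s<j>"``.
    """
    if n_largest == 0:
        return fed
    if len(fed.clients) < n_largest:
        raise ValueError(
            f"federation has {len(fed.clients)} clients, fewer than n_largest={n_largest}"
        )
    # Largest clients by case count; ties broken by site_id for stability.
    ranked = sorted(fed.clients, key=lambda c: (-c.n_cases, c.site_id))
    to_split = {c.site_id for c in ranked[:n_largest]}
    new_clients = []
    for client in fed.clients:
        if client.site_id not in to_split:
            new_clients.append(client)
            continue
        if client.n_cases < n_splits:
            raise ValueError(
                f"client {client.site_id!r} has {client.n_cases} cases, "
                f"cannot split into {n_splits} parts"
            )
        order = sorted(range(client.n_cases), key=lambda i: (client.cases[i].wt_size, i))
        chunks = np.array_split(np.asarray(order), n_splits)
        for j, chunk in enumerate(chunks):
            chunk_cases = [client.cases[i] for i in chunk]
            original_val = set(client.val_indices)
            val_local = [p for p, i in enumerate(chunk) if i in original_val]
            if not val_local:
                # every split part keeps at least one validation case
                val_local = [len(chunk_cases) - 1]
            train_local = [p for p in range(len(chunk_cases)) if p not in val_local]
            new_clients.append(
                ClientDataset(
                    site_id=f"{client.site_id}-s{j}",
                    cases=chunk_cases,
                    train_indices=train_local,
                    val_indices=val_local,
                )
            )
    return Federation(clients=new_clients, partitioning_id="artificial")


def export_cases_nifti(cases: Sequence[Case], out_dir: str | Path) -> list[Path]:
    """Write cases as NIfTI pairs (4-channel image + label map).

    Files are ``<case_id>_image.nii.gz`` (channels stacked on the last
    axis) and ``<case_id>_seg.nii.gz`` with the BraTS label convention,
    for use with the metrics CLI.  2-D cases are written as
    single-slice volumes.
    """
    import nibabel as nib

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written = []
    for case in cases:
        labels = case.labels.values
        image = case.image
        if labels.ndim == 2:
            labels = labels[..., None]
            image = image[..., None]
        # channels last for NIfTI
        img_data = np.moveaxis(image, 0, -1).astype(np.float32)
        zooms = list(case.labels.spacing) + [1.0] * (3 - len(case.labels.spacing))
        affine = np.diag(zooms + [1.0])
        img_path = out_dir / f"{case.case_id}_image.nii.gz"
        seg_path = out_dir / f"{case.case_id}_seg.nii.gz"
        nib.save(nib.Nifti1Image(img_data, affine), img_path)
        nib.save(nib.Nifti1Image(labels.astype(np.int16), affine), seg_path)
        written += [img_path, seg_path]
    return written
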