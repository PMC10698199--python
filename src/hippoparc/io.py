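"""Volumes, atlases, masks and subject tables for the FDG-PET pipeline.

All volumes are NIfTI-1 grids handled through nibabel; no resampling is
done here — masks and atlases must share geometry bit-exactly with the
uptake volumes they are applied to.  Uptake values are dimensionless after
reference (pons) normalization.  Voxel indices are 0-based; world
coordinates come from the affine.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd

__all__ = [
    "UptakeVolume",
    "LabelAtlas",
    "SeedMask",
    "SubjectRecord",
    "ParcelTable",
    "BIOMARKER_CUTOFFS",
    "read_volume",
    "write_volume",
    "read_atlas",
    "read_mask",
    "read_subject_table",
    "write_subject_table",
    "normalize_by_reference",
    "filter_by_resolution",
    "combine_atlases",
    "parcel_means",
    "classify_biomarker_status",
    "mask_volume_mm3",
]

#: CSF Elecsys cut-offs (pg/mL): amyloid-beta(1-42) below the cut-off is
#: amyloid-positive; p-tau / t-tau above their cut-offs are tau-positive.
BIOMARKER_CUTOFFS: dict[str, float] = {"abeta": 977.0, "p_tau": 24.0, "t_tau": 266.0}

GROUPS = ("HC", "earlyMCI", "lateMCI", "AD")


def _voxel_size_from_affine(affine: np.ndarray) -> np.ndarray:
    return np.linalg.norm(affine[:3, :3], axis=0)


@dataclass
class UptakeVolume:
    """One subject's spatially normalized, intensity-normalized uptake grid."""

    grid: np.ndarray
    affine: np.ndarray
    subject_id: str = ""

    def __post_init__(self) -> None:
        self.grid = np.asarray(self.grid, dtype=np.float64)
        self.affine = np.asarray(self.affine, dtype=np.float64)
        if self.grid.ndim != 3:
            raise ValueError("uptake grid must be 3-D")
        if not np.all(np.isfinite(self.affine)):
            raise ValueError("non-finite affine")
        if abs(np.linalg.det(self.affine[:3, :3])) < 1e-12:
            raise ValueError("affine not invertible")

    @property
    def voxel_size(self) -> np.ndarray:
        """Voxel dimensions in mm, from the affine column norms."""
        return _voxel_size_from_affine(self.affine)


@dataclass
class LabelAtlas:
    """Integer label grid (0 = background) with a label lookup table.

    label_table is indexed by label id with columns name, division
    (cortex | subcortex | cerebellum) and hemisphere (L | R | midline).
    """

    grid: np.ndarray
    affine: np.ndarray
    label_table: pd.DataFrame

    def __post_init__(self) -> None:
        self.grid = np.asarray(self.grid)
        if not np.issubdtype(self.grid.dtype, np.integer):
            raise ValueError("atlas grid must be integer-typed")
        if self.grid.min() < 0:
            raise ValueError("atlas labels must be non-negative")
        present = set(np.unique(self.grid)) - {0}
        missing = present - set(self.label_table.index)
        if missing:
            raise ValueError(f"grid labels absent from label_table: {sorted(missing)}")

    @property
    def labels(self) -> np.ndarray:
        """Sorted nonzero labels present in the grid."""
        u = np.unique(self.grid)
        return u[u > 0]


@dataclass
class SeedMask:
    """Boolean voxel mask (seed structure, reference region, or GM mask)."""

    grid: np.ndarray
    affine: np.ndarray
    side: str = "midline"

    def __post_init__(self) -> None:
        self.grid = np.asarray(self.grid).astype(bool)
        if self.grid.ndim != 3:
            raise ValueError("mask grid must be 3-D")
        if not self.grid.any():
            raise ValueError("empty mask")

    @property
    def n_voxels(self) -> int:
        return int(self.grid.sum())


@dataclass
class SubjectRecord:
    """Subject metadata: diagnosis group, native resolution, CSF biomarkers."""

    subject_id: str
    group: str
    native_voxel_size: tuple[float, float, float]
    abeta_42: float | None = None
    p_tau: float | None = None
    t_tau: float | None = None
    bm_status: str = "unknown"

    def __post_init__(self) -> None:
        if self.group not in GROUPS:
            raise ValueError(f"unknown group {self.group!r}")
        for name in ("abeta_42", "p_tau", "t_tau"):
            v = getattr(self, name)
            if v is not None and not (np.isfinite(v) and v > 0):
                raise ValueError(f"{name} must be positive when present, got {v}")


@dataclass
class ParcelTable:
    """Subjects x parcels matrix of mean normalized uptake."""

    values: np.ndarray
    subject_ids: list[str]
    parcel_ids: list[int]
    missing: np.ndarray | None = None  # parcels with no in-mask voxels

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.shape != (len(self.subject_ids), len(self.parcel_ids)):
            raise ValueError("values shape does not match subject/parcel ids")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.subject_ids, columns=self.parcel_ids)


# ---------------------------------------------------------------------------
# NIfTI I/O


def read_volume(path: str | Path, subject_id: str = "") -> UptakeVolume:
    """Read a single-frame 3-D NIfTI uptake volume."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    try:
        img = nib.load(path)
        data = np.asarray(img.dataobj, dtype=np.float64)
    except Exception as exc:  # nibabel raises several unrelated types
        raise ValueError(f"unreadable volume: {path}") from exc
    if data.ndim == 4 and data.shape[3] == 1:
        data = data[..., 0]
    if data.ndim != 3:
        raise ValueError(f"expected a 3-D single-frame volume, got shape {data.shape}")
    return UptakeVolume(grid=data, affine=img.affine, subject_id=subject_id or path.stem)


def write_volume(vol: UptakeVolume, path: str | Path) -> None:
    nib.save(nib.Nifti1Image(vol.grid.astype(np.float64), vol.affine), str(path))


def read_atlas(path: str | Path, label_table: pd.DataFrame) -> LabelAtlas:
    img = nib.load(str(path))
    grid = np.asarray(img.dataobj)
    grid = np.rint(grid).astype(np.int32)
    return LabelAtlas(grid=grid, affine=img.affine, label_table=label_table)


def read_mask(path: str | Path, side: str = "midline") -> SeedMask:
    img = nib.load(str(path))
    return SeedMask(grid=np.asarray(img.dataobj) > 0, affine=img.affine, side=side)


def mask_volume_mm3(mask: SeedMask) -> float:
    """Mask volume in mm^3: voxel count times voxel volume from the affine."""
    return float(mask.n_voxels * np.prod(_voxel_size_from_affine(mask.affine)))


# ---------------------------------------------------------------------------
# Subject tables

_TSV_COLS = ["subject_id", "group", "vx", "vy", "vz", "abeta42", "ptau", "ttau"]


def read_subject_table(path: str | Path) -> list[SubjectRecord]:
    """Read the cohort TSV (subject_id, group, vx, vy, vz, abeta42, ptau, ttau)."""
    df = pd.read_csv(path, sep="\t")
    missing = set(_TSV_COLS) - set(df.columns)
    if missing:
        raise ValueError(f"subject table missing columns: {sorted(missing)}")
    records = []
    for _, row in df.iterrows():
        records.append(
            SubjectRecord(
                subject_id=str(row.subject_id),
                group=str(row.group),
                native_voxel_size=(float(row.vx), float(row.vy), float(row.vz)),
                abeta_42=None if pd.isna(row.abeta42) else float(row.abeta42),
                p_tau=None if pd.isna(row.ptau) else float(row.ptau),
                t_tau=None if pd.isna(row.ttau) else float(row.ttau),
            )
        )
    return records


def write_subject_table(records: list[SubjectRecord], path: str | Path) -> None:
    rows = [
        {
            "subject_id": r.subject_id,
            "group": r.group,
            "vx": r.native_voxel_size[0],
            "vy": r.native_voxel_size[1],
            "vz": r.native_voxel_size[2],
            "abeta42": r.abeta_42,
            "ptau": r.p_tau,
            "ttau": r.t_tau,
        }
        for r in records
    ]
    pd.DataFrame(rows, columns=_TSV_COLS).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Operations


def _check_geometry(a_grid, a_aff, b_grid, b_aff, what: str) -> None:
    if a_grid.shape != b_grid.shape or not np.allclose(a_aff, b_aff):
        raise ValueError(f"geometry mismatch: {what}")


def normalize_by_reference(vol: UptakeVolume, ref: SeedMask) -> UptakeVolume:
    """Divide every voxel by the mean uptake within the reference mask.

    After normalization the mean within the reference region is exactly 1;
    applied to pons this is the standard intensity normalization for FDG
    uptake.  Idempotent and invariant to global rescaling of the input.
    """
    _check_geometry(vol.grid, vol.affine, ref.grid, ref.affine, "volume vs reference mask")
    ref_mean = float(vol.grid[ref.grid].mean())
    if not np.isfinite(ref_mean) or ref_mean <= 0:
        raise ValueError(f"degenerate reference: mean uptake {ref_mean}")
    return UptakeVolume(grid=vol.grid / ref_mean, affine=vol.affine, subject_id=vol.subject_id)


def filter_by_resolution(
    cohort: list[SubjectRecord], max_mm: float = 2.0
) -> list[SubjectRecord]:
    """Keep subjects whose largest native voxel dimension is <= max_mm.

    Mirrors the quality gate that restricts parcellation to high-resolution
    scans; order is preserved.
    """
    kept = [r for r in cohort if max(r.native_voxel_size) <= max_mm]
    if cohort and not kept:
        warnings.warn(f"no subject passes the {max_mm} mm resolution filter", stacklevel=2)
    return kept


def combine_atlases(cortical: LabelAtlas, subcortical: LabelAtlas, offset: int = 400) -> LabelAtlas:
    """Merge cortical and subcortical atlases into one label volume.

    Subcortical labels are shifted by `offset`; where the two atlases
    overlap, the cortical label is zeroed and the subcortical label wins,
    which avoids double-counting voxels in two parcels.
    """
    _check_geometry(cortical.grid, cortical.affine, subcortical.grid, subcortical.affine, "atlases")
    max_cort = int(cortical.grid.max())
    if cortical.label_table.index.size:
        max_cort = max(max_cort, int(cortical.label_table.index.max()))
    if offset < max_cort:
        raise ValueError(f"offset {offset} smaller than max cortical label {max_cort}")
    combined = cortical.grid.copy().astype(np.int32)
    sub = subcortical.grid > 0
    combined[sub] = subcortical.grid[sub].astype(np.int32) + offset
    sub_table = subcortical.label_table.copy()
    sub_table.index = sub_table.index + offset
    tables = [t for t in (cortical.label_table, sub_table) if not t.empty]
    table = pd.concat(tables) if tables else cortical.label_table
    if table.index.has_duplicates:
        raise ValueError("label collision after offset")
    return LabelAtlas(grid=combined, affine=cortical.affine, label_table=table)


def parcel_means(
    vol: UptakeVolume, atlas: LabelAtlas, gm_mask: SeedMask | None = None
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Mean uptake per atlas parcel within the gray-matter mask.

    Returns (means, parcel_ids, missing): parcels with zero in-mask voxels
    get NaN and a True missing flag — flagged, never imputed.
    """
    _check_geometry(vol.grid, vol.affine, atlas.grid, atlas.affine, "volume vs atlas")
    in_mask = np.ones(vol.grid.shape, dtype=bool)
    if gm_mask is not None:
        _check_geometry(vol.grid, vol.affine, gm_mask.grid, gm_mask.affine, "volume vs gm mask")
        in_mask = gm_mask.grid
    parcel_ids = np.asarray(sorted(atlas.label_table.index))
    labels = atlas.grid[in_mask]
    values = vol.grid[in_mask]
    nonzero = labels > 0
    labels, values = labels[nonzero], values[nonzero]
    minlength = int(parcel_ids.max()) + 1 if parcel_ids.size else 1
    counts = np.bincount(labels, minlength=minlength)
    sums = np.bincount(labels, weights=values, minlength=minlength)
    means = np.full(parcel_ids.shape, np.nan)
    present = counts[parcel_ids] > 0
    means[present] = sums[parcel_ids[present]] / counts[parcel_ids[present]]
    return means, parcel_ids, ~present


def classify_biomarker_status(
    rec: SubjectRecord,
    cutoffs: dict[str, float] | None = None,
    rule: str = "amyloid_and_tau",
) -> str:
    """Classify CSF biomarker status as positive / negative / unknown.

    Marker directionality follows standard AD semantics: amyloid-positive
    means abeta_42 below its cut-off, tau-positive means p-tau or t-tau
    above theirs.  Rules combine the per-marker calls with three-valued
    logic, so a status determinable from the available markers is returned
    and "unknown" appears only when the rule cannot be decided.

    rule: "amyloid_and_tau" (default; amyloid AND (p-tau OR t-tau)),
          "any_positive", "all_positive".
    """
    cut = dict(BIOMARKER_CUTOFFS)
    if cutoffs:
        cut.update(cutoffs)

    def call(value: float | None, cutoff: float, positive_below: bool) -> bool | None:
        if value is None:
            return None
        if value < 0:
            raise ValueError("negative biomarker value")
        return (value < cutoff) if positive_below else (value > cutoff)

    amyloid = call(rec.abeta_42, cut["abeta"], positive_below=True)
    ptau = call(rec.p_tau, cut["p_tau"], positive_below=False)
    ttau = call(rec.t_tau, cut["t_tau"], positive_below=False)

    def t_or(a, b):
        if a is True or b is True:
            return True
        if a is None or b is None:
            return None
        return False

    def t_and(a, b):
        if a is False or b is False:
            return False
        if a is None or b is None:
            return None
        return True

    if rule == "amyloid_and_tau":
        status = t_and(amyloid, t_or(ptau, ttau))
    elif rule == "any_positive":
        status = t_or(amyloid, t_or(ptau, ttau))
    elif rule == "all_positive":
        status = t_and(amyloid, t_and(ptau, ttau))
    else:
        raise ValueError(f"unknown biomarker rule {rule!r}")
    if status is None:
        return "unknown"
    return "positive" if status else "negative"


def write_provenance(path: str | Path, **meta) -> None:
    """Write a machine-readable provenance JSON (seeds, cut-offs, rule names)."""
    Path(path).write_text(json.dumps(meta, indent=2, default=str))
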