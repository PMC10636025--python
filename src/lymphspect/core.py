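"""Core data model and I/O for SPECT/CT limb studies.

Volumes are plain 3-D scalar grids (Hounsfield units for CT, activity
counts for SPECT) with millimetre voxel spacing.  CT and SPECT of one
study are assumed co-registered on the same grid; resampling between
mismatched grids is deliberately out of scope.

Conventions
-----------
* voxel indices are 0-based; the proximal end of the limb sits at index 0
  along ``limb_axis`` (default: last axis);
* all lengths in mm, all reported volumes in cm^3;
* the chronicity cut is inclusive: duration >= 12 months => chronic.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd

__all__ = [
    "CHRONIC_MONTHS",
    "ImageVolume",
    "CompartmentMasks",
    "PatientRecord",
    "ContingencyTable",
    "FormatError",
    "SchemaError",
    "read_volume",
    "write_volume",
    "read_mask",
    "write_mask",
    "read_cohort_table",
    "write_cohort_table",
]

#: duration (months) at or above which lymphedema is considered chronic
CHRONIC_MONTHS = 12.0


class FormatError(ValueError):
    """An input file is unreadable or not in a supported format."""


class SchemaError(ValueError):
    """A tabular input lacks a required column or has malformed values."""


@dataclass
class ImageVolume:
    """A 3-D scalar grid with voxel spacing.

    Parameters
    ----------
    voxels : ndarray, shape (nx, ny, nz)
        HU for CT; non-negative activity (counts) for SPECT.
    spacing : tuple of float
        Voxel edge lengths (dx, dy, dz) in mm; all strictly positive.
    modality : {"CT", "SPECT"}
    limb_axis : int
        Grid axis running proximal (index 0) -> distal.
    """

    voxels: np.ndarray
    spacing: tuple[float, float, float]
    modality: str = "CT"
    limb_axis: int = 2

    def __post_init__(self) -> None:
        self.voxels = np.asarray(self.voxels)
        if self.voxels.ndim != 3:
            raise ValueError(f"expected a 3-D grid, got ndim={self.voxels.ndim}")
        if any(s < 2 for s in self.voxels.shape):
            raise ValueError(f"grid needs >= 2 voxels per axis, got {self.voxels.shape}")
        self.spacing = tuple(float(s) for s in self.spacing)
        if len(self.spacing) != 3 or any(s <= 0 for s in self.spacing):
            raise ValueError(f"spacing must be three positive lengths, got {self.spacing}")
        if self.modality not in ("CT", "SPECT"):
            raise ValueError(f"modality must be 'CT' or 'SPECT', got {self.modality!r}")
        if self.modality == "SPECT" and np.any(self.voxels < 0):
            raise ValueError("SPECT activity must be non-negative")
        if not 0 <= self.limb_axis < 3:
            raise ValueError(f"limb_axis must be 0, 1 or 2, got {self.limb_axis}")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.voxels.shape

    @property
    def voxel_volume_mm3(self) -> float:
        dx, dy, dz = self.spacing
        return dx * dy * dz

    def same_grid(self, other: "ImageVolume") -> bool:
        """True when shapes and spacings agree (co-registered pair)."""
        return self.shape == other.shape and np.allclose(
            self.spacing, other.spacing, rtol=0, atol=1e-9
        )


@dataclass
class CompartmentMasks:
    """Boolean compartment masks tied to one limb CT grid.

    The subcutaneous (SC) compartment is *defined* by subtraction:
    ``subcutaneous = limb & ~(bone | muscle)``.  The constructor verifies
    this identity exactly and rejects any mask set violating it, along
    with bone/muscle overlap or masks leaking outside the limb.
    """

    limb: np.ndarray
    bone: np.ndarray
    muscle: np.ndarray
    subcutaneous: np.ndarray

    def __post_init__(self) -> None:
        for name in ("limb", "bone", "muscle", "subcutaneous"):
            m = np.asarray(getattr(self, name))
            if m.dtype != bool:
                m = m.astype(bool)
            setattr(self, name, m)
        shapes = {m.shape for m in (self.limb, self.bone, self.muscle, self.subcutaneous)}
        if len(shapes) != 1:
            raise ValueError(f"masks must share one grid shape, got {shapes}")
        if np.any(self.bone & self.muscle):
            raise ValueError("bone and muscle masks overlap")
        for name in ("bone", "muscle", "subcutaneous"):
            if np.any(getattr(self, name) & ~self.limb):
                raise ValueError(f"{name} mask extends outside the limb mask")
        expected_sc = self.limb & ~(self.bone | self.muscle)
        if np.any(self.subcutaneous != expected_sc):
            raise ValueError(
                "subcutaneous mask violates the subtraction identity "
                "limb & ~(bone | muscle)"
            )

    @classmethod
    def from_limb_bone_muscle(
        cls, limb: np.ndarray, bone: np.ndarray, muscle: np.ndarray
    ) -> "CompartmentMasks":
        """Build masks with SC derived by subtraction (the defining identity)."""
        limb = np.asarray(limb, bool)
        bone = np.asarray(bone, bool) & limb
        muscle = np.asarray(muscle, bool) & limb & ~bone
        sc = limb & ~(bone | muscle)
        return cls(limb=limb, bone=bone, muscle=muscle, subcutaneous=sc)


@dataclass
class PatientRecord:
    """Clinical metadata for one unilateral extremity-lymphedema patient."""

    id: str
    extremity: str  # {"upper", "lower"}
    affected_side: str  # {"left", "right"}
    duration_months: float
    contamination_flag: bool = False
    age: float | None = None
    sex: str | None = None
    bmi: float | None = None
    isl_stage: str | None = None  # descriptive label only, never interpreted
    extras: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.extremity not in ("upper", "lower"):
            raise ValueError(f"extremity must be 'upper' or 'lower', got {self.extremity!r}")
        if self.affected_side not in ("left", "right"):
            raise ValueError(f"affected_side must be 'left' or 'right', got {self.affected_side!r}")
        self.duration_months = float(self.duration_months)
        if self.duration_months < 0:
            raise ValueError("duration_months must be >= 0")

    @property
    def chronic(self) -> bool:
        """Chronic lymphedema: duration of at least one year (inclusive)."""
        return self.duration_months >= CHRONIC_MONTHS


@dataclass
class ContingencyTable:
    """A K x K count table over one ordered category set.

    Orientation follows the staging-comparison convention: rows are the
    second reading (planar + SPECT/CT), columns the first (planar only).
    """

    labels: tuple[str, ...]
    counts: np.ndarray

    def __post_init__(self) -> None:
        self.labels = tuple(str(l) for l in self.labels)
        self.counts = np.asarray(self.counts)
        k = len(self.labels)
        if self.counts.shape != (k, k):
            raise ValueError(
                f"counts shape {self.counts.shape} does not match {k} labels"
            )
        if np.any(self.counts < 0):
            raise ValueError("counts must be non-negative")
        if not np.issubdtype(self.counts.dtype, np.integer):
            if not np.allclose(self.counts, np.round(self.counts)):
                raise ValueError("counts must be integers")
            self.counts = np.round(self.counts).astype(int)

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.counts, index=list(self.labels), columns=list(self.labels))


# ---------------------------------------------------------------------------
# volume I/O (NIfTI via nibabel)
# ---------------------------------------------------------------------------

def write_volume(volume: ImageVolume, path: str | Path) -> None:
    """Write an ImageVolume as NIfTI; spacing goes to the header zooms and
    modality/limb_axis to the header description field."""
    path = Path(path)
    affine = np.diag(list(volume.spacing) + [1.0])
    img = nib.Nifti1Image(volume.voxels, affine)
    img.header.set_zooms(volume.spacing)
    img.header["descrip"] = f"modality={volume.modality};limb_axis={volume.limb_axis}".encode()
    nib.save(img, str(path))


def read_volume(path: str | Path, modality: str | None = None) -> ImageVolume:
    """Read a NIfTI volume.

    ``modality`` overrides whatever the header description carries; a file
    written by :func:`write_volume` round-trips voxels, spacing, modality
    and limb axis.  Missing or unreadable files raise :class:`FormatError`.
    """
    path = Path(path)
    if not path.exists():
        raise FormatError(f"volume file not found: {path}")
    try:
        img = nib.load(str(path))
        voxels = np.asarray(img.dataobj)
    except Exception as exc:  # nibabel raises a zoo of error types
        raise FormatError(f"cannot read {path} as a NIfTI volume: {exc}") from exc
    if voxels.ndim != 3:
        raise FormatError(f"{path}: expected a 3-D volume, got ndim={voxels.ndim}")
    spacing = tuple(float(z) for z in img.header.get_zooms()[:3])
    descrip = img.header["descrip"].tobytes().split(b"\x00")[0].decode(errors="replace")
    meta = dict(
        item.split("=", 1) for item in descrip.split(";") if "=" in item
    )
    limb_axis = int(meta.get("limb_axis", 2))
    if modality is None:
        modality = meta.get("modality", "CT")
    return ImageVolume(voxels=voxels, spacing=spacing, modality=modality, limb_axis=limb_axis)


def write_mask(mask: np.ndarray, spacing: tuple[float, float, float], path: str | Path) -> None:
    """Write a boolean mask as a uint8 NIfTI volume."""
    affine = np.diag(list(spacing) + [1.0])
    img = nib.Nifti1Image(np.asarray(mask, np.uint8), affine)
    img.header.set_zooms(spacing)
    nib.save(img, str(path))


def read_mask(path: str | Path) -> tuple[np.ndarray, tuple[float, float, float]]:
    """Read a mask NIfTI; returns (bool grid, spacing)."""
    vol = read_volume(path, modality="CT")
    return vol.voxels.astype(bool), vol.spacing


# ---------------------------------------------------------------------------
# cohort table I/O (CSV via pandas)
# ---------------------------------------------------------------------------

_REQUIRED_COLUMNS = ("id", "extremity", "affected_side", "duration_months")
_KNOWN_COLUMNS = _REQUIRED_COLUMNS + (
    "contamination_flag", "age", "sex", "bmi", "isl_stage",
)


def read_cohort_table(path: str | Path) -> list[PatientRecord]:
    """Read a patient table (CSV with a header).

    Required columns: id, extremity, affected_side, duration_months.
    Optional: contamination_flag, age, sex, bmi, isl_stage.  Unknown
    columns are preserved verbatim in ``record.extras``.
    """
    path = Path(path)
    if not path.exists():
        raise FormatError(f"cohort table not found: {path}")
    df = pd.read_csv(path)
    for col in _REQUIRED_COLUMNS:
        if col not in df.columns:
            raise SchemaError(f"cohort table {path} is missing required column {col!r}")
    records = []
    extra_cols = [c for c in df.columns if c not in _KNOWN_COLUMNS]
    for _, row in df.iterrows():
        records.append(
            PatientRecord(
                id=str(row["id"]),
                extremity=str(row["extremity"]),
                affected_side=str(row["affected_side"]),
                duration_months=float(row["duration_months"]),
                contamination_flag=bool(row.get("contamination_flag", False)),
                age=None if pd.isna(row.get("age", np.nan)) else float(row["age"]),
                sex=None if pd.isna(row.get("sex", np.nan)) else str(row["sex"]),
                bmi=None if pd.isna(row.get("bmi", np.nan)) else float(row["bmi"]),
                isl_stage=None if pd.isna(row.get("isl_stage", np.nan)) else str(row["isl_stage"]),
                extras={c: row[c] for c in extra_cols},
            )
        )
    return records


def write_cohort_table(records: list[PatientRecord], path: str | Path) -> None:
    rows = []
    for r in records:
        d = dataclasses.asdict(r)
        extras = d.pop("extras")
        d.update(extras)
        rows.append(d)
    pd.DataFrame(rows).to_csv(path, index=False)
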