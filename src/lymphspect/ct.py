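"""CT-side quantification: compartment segmentation, honeycomb-pattern
(HP) volumetry and volumetric severity grading.

The honeycomb pattern — trabeculated fibrotic/fluid strands inside the
subcutaneous fat of a lymphedematous limb — is operationalized as the
subcutaneous voxels falling inside a Hounsfield window (default -60..10 HU,
both bounds inclusive).  The HP volume ratio is V_HP / V_SC of the
affected extremity.

Clinical severity is graded from the CT volumetric difference
100 * (V_affected - V_unaffected) / V_unaffected with half-open bands:
Grade 0 < 10%, Grade 1 [10, 20)%, Grade 2 [20, 30)%, Grade 3 [30, 40)%,
Grade 4 >= 40%.  A negative difference clamps to Grade 0 with a warning.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .core import CompartmentMasks, ImageVolume

__all__ = [
    "CtQuantConfig",
    "VolumetryResult",
    "SeedError",
    "segment_limb",
    "segment_compartments",
    "compute_volume",
    "hp_ratio",
    "volumetric_grade",
    "GRADE_BANDS",
]

#: lower edges (percent) of severity grades 1..4; below 10% is Grade 0
GRADE_BANDS = (10.0, 20.0, 30.0, 40.0)


class SeedError(ValueError):
    """A region-growing seed sits in an invalid location (e.g. air)."""


@dataclass
class CtQuantConfig:
    """Tunable CT segmentation/quantification parameters.

    The limb is grown from a soft-tissue seed as the connected component
    of voxels above ``limb_hu_threshold`` (separates tissue from air).
    Bone is thresholded at ``bone_hu_min`` then morphologically closed;
    muscle is the HU window ``muscle_hu_window`` interior to the
    subcutaneous fat ring, cleaned by closing and hole filling.  The
    commercial tool used clinically publishes none of these values, so
    they are configuration, validated against phantom ground truth.
    """

    limb_hu_threshold: float = -400.0
    seed_min_hu: float = -300.0
    bone_hu_min: float = 150.0
    muscle_hu_window: tuple[float, float] = (20.0, 100.0)
    hp_window: tuple[float, float] = (-60.0, 10.0)  # inclusive bounds
    closing_radius_mm: float = 3.0
    min_component_voxels: int = 27
    #: fractions of the limb axis cropped at the proximal/distal ends,
    #: standing in for the anatomical boundary landmarks (phantom: 0, 0)
    crop_fractions: tuple[float, float] = (0.0, 0.0)

    def __post_init__(self) -> None:
        lo, hi = self.hp_window
        if not lo < hi:
            raise ValueError(f"hp_window must satisfy lo < hi, got {self.hp_window}")
        for v in (self.limb_hu_threshold, self.bone_hu_min, lo, hi, *self.muscle_hu_window):
            if not np.isfinite(v):
                raise ValueError("all HU thresholds must be finite")


def _ball(radius_mm: float, spacing: tuple[float, float, float]) -> np.ndarray:
    """Anisotropy-aware ellipsoidal structuring element."""
    r = [max(1, int(round(radius_mm / s))) for s in spacing]
    zz, yy, xx = np.ogrid[-r[0]:r[0] + 1, -r[1]:r[1] + 1, -r[2]:r[2] + 1]
    return (zz / r[0]) ** 2 + (yy / r[1]) ** 2 + (xx / r[2]) ** 2 <= 1.0


def segment_limb(ct: ImageVolume, seed_point: tuple[int, int, int],
                 cfg: CtQuantConfig | None = None) -> np.ndarray:
    """Region-grow the limb from a soft-tissue seed.

    Returns the single connected component of above-threshold voxels
    containing the seed, cropped along the limb axis per
    ``cfg.crop_fractions``.  Seeds in air raise :class:`SeedError`.
    """
    cfg = cfg or CtQuantConfig()
    seed = tuple(int(i) for i in seed_point)
    hu = ct.voxels
    if hu[seed] <= cfg.seed_min_hu:
        raise SeedError(
            f"seed {seed} has HU {hu[seed]:.0f} <= {cfg.seed_min_hu:.0f}; "
            "place the seed inside soft tissue"
        )
    tissue = hu >= cfg.limb_hu_threshold
    if not tissue[seed]:
        raise SeedError(f"seed {seed} falls below the limb threshold "
                        f"{cfg.limb_hu_threshold:.0f} HU")
    labels, _ = ndimage.label(tissue)
    mask = labels == labels[seed]
    lo_frac, hi_frac = cfg.crop_fractions
    if lo_frac > 0 or hi_frac > 0:
        n = mask.shape[ct.limb_axis]
        lo, hi = int(round(lo_frac * n)), n - int(round(hi_frac * n))
        keep = np.zeros(n, bool)
        keep[lo:hi] = True
        shape = [1, 1, 1]
        shape[ct.limb_axis] = n
        mask = mask & keep.reshape(shape)
    return mask


def segment_compartments(ct: ImageVolume, limb_mask: np.ndarray,
                         cfg: CtQuantConfig | None = None) -> CompartmentMasks:
    """Threshold-and-clean bone and muscle inside the limb; subcutaneous
    fat follows by subtraction (the defining identity, asserted by the
    :class:`CompartmentMasks` constructor)."""
    cfg = cfg or CtQuantConfig()
    limb_mask = np.asarray(limb_mask, bool)
    if not limb_mask.any():
        raise ValueError("limb mask is empty")
    hu = ct.voxels
    selem = _ball(cfg.closing_radius_mm, ct.spacing)

    bone = (hu >= cfg.bone_hu_min) & limb_mask
    if bone.any():
        bone = ndimage.binary_closing(bone, structure=selem) & limb_mask
        bone = _drop_specks(bone, cfg.min_component_voxels)

    lo, hi = cfg.muscle_hu_window
    muscle = (hu >= lo) & (hu <= hi) & limb_mask & ~bone
    if muscle.any():
        muscle = ndimage.binary_closing(muscle, structure=selem)
        muscle = ndimage.binary_fill_holes(muscle)
        muscle = _drop_specks(muscle, cfg.min_component_voxels)
        # keep muscle interior to the subcutaneous fat ring: voxels of the
        # cleaned window that can reach the limb surface through fat are
        # speckle, not muscle, and the fill/closing already removed most —
        # the remaining constraint is simply staying inside the limb and
        # off the bone
        muscle = muscle & limb_mask & ~bone

    return CompartmentMasks.from_limb_bone_muscle(limb_mask, bone, muscle)


def _drop_specks(mask: np.ndarray, min_voxels: int) -> np.ndarray:
    labels, n = ndimage.label(mask)
    if n == 0:
        return mask
    sizes = np.bincount(labels.ravel())
    sizes[0] = 0
    keep = np.flatnonzero(sizes >= min_voxels)
    return np.isin(labels, keep)


def compute_volume(mask: np.ndarray, spacing: tuple[float, float, float]) -> float:
    """Mask volume in cm^3: true-voxel count x voxel volume (mm^3 -> cm^3)."""
    dx, dy, dz = spacing
    return float(np.count_nonzero(mask)) * dx * dy * dz / 1000.0


def hp_ratio(ct: ImageVolume, sc_mask: np.ndarray,
             cfg: CtQuantConfig | None = None) -> tuple[np.ndarray, float, float]:
    """Honeycomb-pattern mask, volume and ratio over the SC compartment.

    hp_mask = SC voxels with hp_lo <= HU <= hp_hi (inclusive);
    ratio = V_HP / V_SC in [0, 1].  An empty SC mask is an error — the
    ratio is undefined, never silently zero.
    """
    cfg = cfg or CtQuantConfig()
    sc_mask = np.asarray(sc_mask, bool)
    if not sc_mask.any():
        raise ValueError("SC mask is empty: HP volume ratio is undefined")
    lo, hi = cfg.hp_window
    hp_mask = sc_mask & (ct.voxels >= lo) & (ct.voxels <= hi)
    v_hp = compute_volume(hp_mask, ct.spacing)
    v_sc = compute_volume(sc_mask, ct.spacing)
    return hp_mask, v_hp, v_hp / v_sc


@dataclass(frozen=True)
class VolumetryResult:
    """CT volumetry of one affected/unaffected limb pair."""

    volume_affected_cm3: float
    volume_unaffected_cm3: float
    ct_diff_percent: float
    severity_grade: int

    def __post_init__(self) -> None:
        if self.severity_grade != grade_from_percent(self.ct_diff_percent):
            raise ValueError("severity_grade inconsistent with ct_diff_percent")


def grade_from_percent(percent: float) -> int:
    """Map a volumetric-difference percent to severity grade 0..4.

    Bands are half-open: boundary values 10/20/30/40 map to the higher
    grade; negative differences are Grade 0.
    """
    grade = 0
    for g, edge in enumerate(GRADE_BANDS, start=1):
        if percent >= edge:
            grade = g
    return grade


def volumetric_grade(v_affected_cm3: float, v_unaffected_cm3: float) -> VolumetryResult:
    """CT volumetric difference percent and its severity grade."""
    if v_unaffected_cm3 <= 0:
        raise ValueError(f"unaffected-limb volume must be > 0, got {v_unaffected_cm3}")
    percent = 100.0 * (v_affected_cm3 - v_unaffected_cm3) / v_unaffected_cm3
    if percent < 0:
        warnings.warn(
            f"affected limb smaller than unaffected ({percent:.1f}%); grading as 0",
            stacklevel=2,
        )
    return VolumetryResult(
        volume_affected_cm3=float(v_affected_cm3),
        volume_unaffected_cm3=float(v_unaffected_cm3),
        ct_diff_percent=float(percent),
        severity_grade=grade_from_percent(percent),
    )
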