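"""Synthetic paired CT/SPECT limb phantom with ground truth.

The generator emulates the imaging substrate of a SPECT/CT
lymphoscintigraphy study: a tapered cylindrical limb with bone, muscle
and subcutaneous (SC) fat compartments and conventional radiology HU
statistics; a honeycomb-pattern (HP) texture of connected strands inside
the SC fat, hitting a target voxel fraction per region inside the
-60..10 HU window; dermal-backflow (DBF) activity painted as a dermal
rim of the SC shell in flagged regions; nodal/duct/injection-site
hotspots; a gamma-camera point-spread function (isotropic Gaussian) and
Poisson counting noise on SPECT; Gaussian noise and per-tissue texture
on CT.  Every study ships its ground truth (masks, findings, stage,
class, volumes), making the phantom the oracle for recovery tests.

Lymphedema severity enters through the CT volumetric difference: the
affected limb's outer radius is scaled by sqrt(1 + d/100), which inflates
the SC compartment and raises the total limb volume by exactly d percent
relative to the unaffected geometry (interior compartments unchanged).
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .core import CompartmentMasks, ImageVolume, PatientRecord
from .ct import grade_from_percent
from .staging import (
    FindingsRecord,
    HybridClass,
    RegionPattern,
    TLSStage,
    hybrid_classify,
    region_pattern,
    tls_stage,
)

__all__ = [
    "InfeasibleSpecError",
    "RegionDbfSpec",
    "PhantomNoise",
    "PhantomSpec",
    "PhantomTruth",
    "PhantomStudy",
    "PlanarReadingModel",
    "DEFAULT_SEVERITY_COUPLING",
    "DEFAULT_DURATION_COUPLING",
    "generate_phantom",
    "generate_cohort",
]

REGIONS = ("proximal", "distal")


class InfeasibleSpecError(ValueError):
    """The requested HP/DBF load does not fit in the SC compartment."""


@dataclass
class RegionDbfSpec:
    """DBF request for one limb region: a dermal rim of given thickness
    and activity painted on the outer SC shell."""

    present: bool = False
    rim_thickness_mm: float = 12.0
    activity: float = 200.0


@dataclass
class PhantomNoise:
    """Noise/PSF model: per-tissue HU texture is part of the tissue
    definitions; these are the acquisition terms."""

    ct_noise_sd_hu: float = 5.0
    spect_background: float = 4.0
    psf_fwhm_mm: float = 8.0  # typical LEHR system resolution
    poisson: bool = True


@dataclass
class PhantomSpec:
    """Full parameterization of one limb phantom (seed determines output)."""

    extremity: str = "lower"
    shape: tuple[int, int, int] = (96, 96, 96)
    spacing: tuple[float, float, float] = (2.0, 2.0, 2.0)
    proximal_radius_mm: float = 44.0
    distal_radius_mm: float = 28.0
    bone_radius_frac: float = 0.18
    muscle_radius_frac: float = 0.55
    #: (mean, sd) HU per tissue; sd is biological/texture variation
    hu_stats: dict = field(default_factory=lambda: {
        "air": (-1000.0, 20.0),
        "fat": (-100.0, 15.0),
        "muscle": (50.0, 10.0),
        "bone": (700.0, 100.0),
    })
    hp_fraction_target: dict = field(default_factory=lambda: {"proximal": 0.0, "distal": 0.0})
    hp_window: tuple[float, float] = (-60.0, 10.0)
    hp_texture_smoothing_mm: float = 4.0
    dbf: dict = field(default_factory=lambda: {
        "proximal": RegionDbfSpec(), "distal": RegionDbfSpec(),
    })
    #: fraction of each region's axial span kept clear of rim at both ends,
    #: so truth DBF never abuts the split plane or the limb ends
    rim_axial_margin_frac: float = 0.12
    proximal_ln_visible: bool = True
    intermediate_ln_visible: bool = False
    ducts_visible: bool = True
    injection_depot: bool = True
    node_activity: float = 400.0
    duct_activity: float = 100.0
    depot_activity: float = 3000.0
    ct_volume_diff_percent: float = 0.0
    region_split_fraction: float = 0.5
    noise: PhantomNoise = field(default_factory=PhantomNoise)
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 < self.bone_radius_frac < self.muscle_radius_frac < 1.0:
            raise ValueError(
                "compartment radius fractions must be strictly increasing and < 1"
            )
        for region, f in self.hp_fraction_target.items():
            if not 0.0 <= f <= 1.0:
                raise InfeasibleSpecError(
                    f"hp_fraction_target[{region!r}] = {f} outside [0, 1]"
                )
        if self.ct_volume_diff_percent <= -100.0 * (1 - self.muscle_radius_frac ** 2):
            raise ValueError("volume deficit would collapse the SC compartment")


@dataclass
class PhantomTruth:
    """Ground truth emitted with each phantom (the oracle for recovery)."""

    masks: CompartmentMasks
    region_masks: dict
    hp_mask: np.ndarray
    hp_fractions: dict
    dbf_masks: dict
    dbf_mask: np.ndarray
    hotspot_mask: np.ndarray
    exclusion_mask: np.ndarray
    findings: FindingsRecord
    patterns: dict
    tls: TLSStage
    hybrid_class: HybridClass
    volumes: dict
    ct_diff_percent: float
    severity_grade: int


def _radius_profile(spec: PhantomSpec, nz: int, dz: float) -> np.ndarray:
    z = np.arange(nz) * dz
    length = max((nz - 1) * dz, 1e-9)
    return spec.proximal_radius_mm + (
        spec.distal_radius_mm - spec.proximal_radius_mm
    ) * z / length


def generate_phantom(spec: PhantomSpec) -> tuple[ImageVolume, ImageVolume, PhantomTruth]:
    """Generate one co-registered CT/SPECT pair plus ground truth.

    Deterministic under ``spec.seed``: the same spec yields bit-identical
    volumes.  Raises :class:`InfeasibleSpecError` when the requested DBF
    rim does not fit inside the SC shell.
    """
    rng = np.random.default_rng(spec.seed)
    nx, ny, nz = spec.shape
    dx, dy, dz = spec.spacing

    # --- geometry -----------------------------------------------------
    x = (np.arange(nx) - (nx - 1) / 2.0) * dx
    y = (np.arange(ny) - (ny - 1) / 2.0) * dy
    rho = np.sqrt(x[:, None] ** 2 + y[None, :] ** 2)  # (nx, ny)
    r0 = _radius_profile(spec, nz, dz)  # (nz,) unaffected outer radius
    scale = float(np.sqrt(1.0 + spec.ct_volume_diff_percent / 100.0))
    limb_r = scale * r0
    rho3 = rho[:, :, None]
    limb = rho3 <= limb_r[None, None, :]
    bone = rho3 <= (spec.bone_radius_frac * r0)[None, None, :]
    muscle = (rho3 <= (spec.muscle_radius_frac * r0)[None, None, :]) & ~bone
    masks = CompartmentMasks.from_limb_bone_muscle(limb, bone, muscle)
    sc = masks.subcutaneous

    zidx = np.arange(nz)
    cut = int(round(spec.region_split_fraction * nz))
    in_proximal = (zidx < cut).reshape(1, 1, nz)
    region_masks = {"proximal": limb & in_proximal, "distal": limb & ~in_proximal}
    region_z = {"proximal": (0, cut), "distal": (cut, nz)}

    # --- HP texture: smoothed random field thresholded per region -----
    sigma_hp = [spec.hp_texture_smoothing_mm / s for s in spec.spacing]
    hp_field = ndimage.gaussian_filter(rng.standard_normal(spec.shape), sigma=sigma_hp)
    hp_mask = np.zeros(spec.shape, bool)
    hp_fractions = {}
    for region in REGIONS:
        target = float(spec.hp_fraction_target.get(region, 0.0))
        region_sc = sc & region_masks[region]
        n_sc = int(region_sc.sum())
        k = int(round(target * n_sc))
        if k > 0:
            flat = np.flatnonzero(region_sc.ravel())
            vals = hp_field.ravel()[flat]
            top = flat[np.argpartition(vals, -k)[-k:]]
            hp_mask.ravel()[top] = True
        hp_fractions[region] = (k / n_sc) if n_sc else 0.0

    # --- CT image -----------------------------------------------------
    mean_map = np.full(spec.shape, spec.hu_stats["air"][0])
    sd_map = np.full(spec.shape, spec.hu_stats["air"][1])
    for tissue, mask in (("fat", sc), ("muscle", muscle), ("bone", bone)):
        mean_map[mask] = spec.hu_stats[tissue][0]
        sd_map[mask] = spec.hu_stats[tissue][1]
    lo, hi = spec.hp_window
    ct_vox = mean_map + sd_map * rng.standard_normal(spec.shape)
    ct_vox[hp_mask] = rng.uniform(lo, hi, size=int(hp_mask.sum()))
    if spec.noise.ct_noise_sd_hu > 0:
        ct_vox += spec.noise.ct_noise_sd_hu * rng.standard_normal(spec.shape)

    # --- SPECT activity ----------------------------------------------
    act = np.zeros(spec.shape)
    act[limb] = spec.noise.spect_background

    margin = spec.rim_axial_margin_frac
    dbf_masks = {}
    for region in REGIONS:
        rspec = spec.dbf.get(region, RegionDbfSpec(present=False))
        if not rspec.present:
            dbf_masks[region] = np.zeros(spec.shape, bool)
            continue
        inner = limb_r - rspec.rim_thickness_mm
        if np.any(inner[region_z[region][0]:region_z[region][1]]
                  < spec.muscle_radius_frac * r0[region_z[region][0]:region_z[region][1]]):
            raise InfeasibleSpecError(
                f"DBF rim of {rspec.rim_thickness_mm} mm exceeds the SC shell "
                f"thickness in the {region} region"
            )
        z_lo, z_hi = region_z[region]
        span = z_hi - z_lo
        band = np.zeros(nz, bool)
        band[z_lo + int(round(margin * span)):z_hi - int(round(margin * span))] = True
        rim = sc & (rho3 >= inner[None, None, :]) & band.reshape(1, 1, nz)
        act[rim] = rspec.activity
        dbf_masks[region] = rim

    # hotspots: lymph nodes deep to the SC, a linear duct in the inner SC,
    # and the injection-site depot at the distal tip near the surface
    hotspots = {}

    def _sphere(center_mm: tuple[float, float, float], radius_mm: float) -> np.ndarray:
        cz = np.arange(nz) * dz
        d2 = ((x[:, None, None] - center_mm[0]) ** 2
              + (y[None, :, None] - center_mm[1]) ** 2
              + (cz[None, None, :] - center_mm[2]) ** 2)
        return d2 <= radius_mm ** 2

    # each hotspot also gets an analytically enlarged exclusion zone that
    # covers its PSF smear (the depot is orders brighter, gets more margin)
    _EXCL_LN, _EXCL_DUCT, _EXCL_DEPOT = 12.0, 12.0, 15.0
    exclusions = {}
    length = (nz - 1) * dz
    if spec.proximal_ln_visible:
        z_ln = 0.05 * length
        r_here = float(np.interp(z_ln, np.arange(nz) * dz, r0))
        center = (0.3 * spec.muscle_radius_frac * r_here, 0.0, z_ln)
        hotspots["proximal_ln"] = _sphere(center, 7.0)
        exclusions["proximal_ln"] = _sphere(center, 7.0 + _EXCL_LN)
    if spec.intermediate_ln_visible:
        z_ln = 0.47 * length
        r_here = float(np.interp(z_ln, np.arange(nz) * dz, r0))
        center = (-0.3 * spec.muscle_radius_frac * r_here, 0.0, z_ln)
        hotspots["intermediate_ln"] = _sphere(center, 7.0)
        exclusions["intermediate_ln"] = _sphere(center, 7.0 + _EXCL_LN)
    if spec.ducts_visible:
        # thin tube along the limb axis in the inner SC (x > 0 side)
        duct_rho = spec.muscle_radius_frac * r0 + 0.3 * (limb_r - spec.muscle_radius_frac * r0)
        d2 = (x[:, None, None] - duct_rho[None, None, :]) ** 2 + (y[None, :, None]) ** 2
        band = ((zidx >= 0.08 * nz) & (zidx <= 0.92 * nz)).reshape(1, 1, nz)
        zmargin = int(np.ceil(_EXCL_DUCT / dz))
        band_x = ((zidx >= 0.08 * nz - zmargin) & (zidx <= 0.92 * nz + zmargin)).reshape(1, 1, nz)
        hotspots["duct"] = (d2 <= 2.5 ** 2) & band & limb
        exclusions["duct"] = (d2 <= (2.5 + _EXCL_DUCT) ** 2) & band_x
    if spec.injection_depot:
        z_dep = 0.97 * length
        r_here = scale * float(np.interp(z_dep, np.arange(nz) * dz, r0))
        center = (0.8 * r_here, 0.0, z_dep)
        hotspots["depot"] = _sphere(center, 6.0) & limb
        exclusions["depot"] = _sphere(center, 6.0 + _EXCL_DEPOT)

    activity_of = {"proximal_ln": spec.node_activity, "intermediate_ln": spec.node_activity,
                   "duct": spec.duct_activity, "depot": spec.depot_activity}
    hotspot_mask = np.zeros(spec.shape, bool)
    for name, mask in hotspots.items():
        act[mask] = activity_of[name]
        hotspot_mask |= mask
    for region in REGIONS:  # truth DBF stays disjoint from hotspots
        dbf_masks[region] &= ~hotspot_mask
    dbf_mask = dbf_masks["proximal"] | dbf_masks["distal"]

    exclusion = np.zeros(spec.shape, bool)
    for mask in exclusions.values():
        exclusion |= mask

    sigma_psf = [spec.noise.psf_fwhm_mm / 2.3548 / s for s in spec.spacing]
    act = ndimage.gaussian_filter(act, sigma=sigma_psf)
    if spec.noise.poisson:
        act = rng.poisson(np.clip(act, 0, None)).astype(float)

    ct = ImageVolume(ct_vox, spec.spacing, modality="CT")
    spect = ImageVolume(act, spec.spacing, modality="SPECT")

    # --- truth labels -------------------------------------------------
    present = {r: bool(dbf_masks[r].any()) for r in REGIONS}
    if present["proximal"] and present["distal"]:
        extent = "entire"
    elif present["proximal"]:
        extent = "proximal"
    elif present["distal"]:
        extent = "distal"
    else:
        extent = "none"
    findings = FindingsRecord(
        dbf_extent=extent,
        proximal_ln_visible=spec.proximal_ln_visible,
        intermediate_ln_visible=spec.intermediate_ln_visible,
        ducts_visible=spec.ducts_visible,
        reading="planar+SPECT/CT",
    )
    patterns = {
        r: region_pattern(present[r], spec.hp_fraction_target.get(r, 0.0) >= 0.05, region=r)
        for r in REGIONS
    }
    voxel_cm3 = dx * dy * dz / 1000.0
    volumes = {
        "limb_cm3": float(limb.sum()) * voxel_cm3,
        "sc_cm3": float(sc.sum()) * voxel_cm3,
        "hp_cm3": float(hp_mask.sum()) * voxel_cm3,
        "dbf_cm3": float(dbf_mask.sum()) * voxel_cm3,
    }
    truth = PhantomTruth(
        masks=masks,
        region_masks=region_masks,
        hp_mask=hp_mask,
        hp_fractions=hp_fractions,
        dbf_masks=dbf_masks,
        dbf_mask=dbf_mask,
        hotspot_mask=hotspot_mask,
        exclusion_mask=exclusion,
        findings=findings,
        patterns=patterns,
        tls=tls_stage(findings),
        # nearest policy: covered pairs classify identically to strict, and
        # a custom spec whose pattern pair the five classes do not cover
        # still gets a truth label (tagged imputed)
        hybrid_class=hybrid_classify(patterns["proximal"], patterns["distal"], policy="nearest"),
        volumes=volumes,
        ct_diff_percent=spec.ct_volume_diff_percent,
        severity_grade=grade_from_percent(spec.ct_volume_diff_percent),
    )
    return ct, spect, truth


# ---------------------------------------------------------------------------
# cohort generation: hybrid class drives patterns, stage and severity
# ---------------------------------------------------------------------------

#: class -> uniform (lo, hi) of the CT volumetric difference percent.
#: Monotone location with overlap; Class 1 stays below the Grade 0/1 edge
#: by construction.  Classes 4 and 5 overlap (late disease either way).
DEFAULT_SEVERITY_COUPLING = {
    1: (1.0, 8.0),
    2: (5.0, 14.0),
    3: (12.0, 26.0),
    4: (24.0, 42.0),
    5: (30.0, 48.0),
}

#: class -> uniform (lo, hi) duration in months (later classes are
#: longer-standing disease; the chronicity cut is 12 months)
DEFAULT_DURATION_COUPLING = {
    1: (2.0, 24.0),
    2: (3.0, 36.0),
    3: (6.0, 72.0),
    4: (12.0, 120.0),
    5: (18.0, 150.0),
}


@dataclass
class PlanarReadingModel:
    """Emulates how a planar-only reading degrades the SPECT/CT truth:
    small probabilities of missing DBF in one region or a node station,
    and of clothing contamination mimicking an intermediate node."""

    p_miss_dbf: float = 0.10
    p_miss_proximal_ln: float = 0.05
    p_miss_intermediate_ln: float = 0.08
    p_contamination: float = 0.05


@dataclass
class PhantomStudy:
    """One synthetic subject: paired limbs, truth, and both readings."""

    record: PatientRecord
    spec: PhantomSpec
    ct_affected: ImageVolume
    spect_affected: ImageVolume
    truth: PhantomTruth
    ct_unaffected: ImageVolume
    spect_unaffected: ImageVolume
    truth_unaffected: PhantomTruth
    planar_findings: FindingsRecord
    combined_findings: FindingsRecord


def _class_layout(cls: int, rng: np.random.Generator) -> dict:
    """Coupling table: hybrid class -> per-region DBF flags, HP targets and
    node/duct visibility (stage follows through the default rule table:
    1 -> P-1, 2 -> P-2, 3 -> P-3, 4 -> T-5, 5 -> T-6)."""
    side = str(rng.choice(["proximal", "distal"]))
    other = "distal" if side == "proximal" else "proximal"
    if cls == 1:
        return dict(dbf={}, hp={}, prox_ln=True, inter_ln=False, ducts=True)
    if cls == 2:
        return dict(dbf={side}, hp={}, prox_ln=True, inter_ln=False, ducts=False)
    if cls == 3:
        lo_p, hi_p = 0.10, 0.30
        return dict(dbf={"proximal", "distal"},
                    hp={"proximal": rng.uniform(lo_p, hi_p), "distal": rng.uniform(lo_p, hi_p)},
                    prox_ln=True, inter_ln=True, ducts=False)
    if cls == 4:
        return dict(dbf={side},
                    hp={"proximal": rng.uniform(0.15, 0.35), "distal": rng.uniform(0.15, 0.35)},
                    prox_ln=False, inter_ln=False, ducts=False)
    if cls == 5:
        return dict(dbf=set(),
                    hp={"proximal": rng.uniform(0.20, 0.40), "distal": rng.uniform(0.20, 0.40)},
                    prox_ln=False, inter_ln=False, ducts=False)
    raise ValueError(f"unknown class {cls}")


def _degrade_planar(findings: FindingsRecord, model: PlanarReadingModel,
                    rng: np.random.Generator) -> tuple[FindingsRecord, bool]:
    """Derive the planar-only reading from the SPECT/CT truth."""
    extent = findings.dbf_extent
    if extent != "none" and rng.random() < model.p_miss_dbf:
        if extent == "entire":
            extent = str(rng.choice(["proximal", "distal"]))
        else:
            extent = "none"
    prox_ln = findings.proximal_ln_visible and not rng.random() < model.p_miss_proximal_ln
    inter_ln = findings.intermediate_ln_visible and not rng.random() < model.p_miss_intermediate_ln
    contaminated = rng.random() < model.p_contamination
    if contaminated:
        inter_ln = True  # clothing artifact read as an intermediate node
    planar = FindingsRecord(
        dbf_extent=extent,
        proximal_ln_visible=prox_ln,
        intermediate_ln_visible=inter_ln,
        ducts_visible=findings.ducts_visible,
        contamination_flag=contaminated,
        reading="planar",
    )
    return planar, contaminated


def generate_cohort(n: int, class_mix: dict | None = None, seed: int = 0,
                    base_spec: PhantomSpec | None = None,
                    severity_coupling: dict | None = None,
                    duration_coupling: dict | None = None,
                    planar_model: PlanarReadingModel | None = None) -> list[PhantomStudy]:
    """Generate ``n`` affected/unaffected limb pairs with class-coupled
    severity, duration and findings; reproducible under ``seed``.

    ``class_mix`` maps hybrid classes 1..5 to sampling probabilities
    (default: the uniform mix).
    """
    if n <= 0:
        raise ValueError(f"cohort size must be positive, got {n}")
    class_mix = class_mix or {c: 0.2 for c in (1, 2, 3, 4, 5)}
    classes = sorted(class_mix)
    probs = np.array([class_mix[c] for c in classes], float)
    if np.any(probs < 0) or probs.sum() <= 0:
        raise ValueError("class_mix must be a distribution over classes 1..5")
    probs = probs / probs.sum()
    severity_coupling = severity_coupling or DEFAULT_SEVERITY_COUPLING
    duration_coupling = duration_coupling or DEFAULT_DURATION_COUPLING
    planar_model = planar_model or PlanarReadingModel()
    base = base_spec or PhantomSpec()
    rng = np.random.default_rng(seed)

    studies = []
    for i in range(n):
        cls = int(rng.choice(classes, p=probs))
        layout = _class_layout(cls, rng)
        diff = float(rng.uniform(*severity_coupling[cls]))
        duration = float(rng.uniform(*duration_coupling[cls]))
        spec_aff = dataclasses.replace(
            base,
            hp_fraction_target={r: float(layout["hp"].get(r, 0.0)) for r in REGIONS},
            dbf={r: RegionDbfSpec(present=(r in layout["dbf"])) for r in REGIONS},
            proximal_ln_visible=layout["prox_ln"],
            intermediate_ln_visible=layout["inter_ln"],
            ducts_visible=layout["ducts"],
            ct_volume_diff_percent=diff,
            seed=int(rng.integers(0, 2**31 - 1)),
        )
        spec_unaff = dataclasses.replace(
            base,
            hp_fraction_target={r: 0.0 for r in REGIONS},
            dbf={r: RegionDbfSpec(present=False) for r in REGIONS},
            proximal_ln_visible=True,
            intermediate_ln_visible=True,
            ducts_visible=True,
            ct_volume_diff_percent=0.0,
            seed=int(rng.integers(0, 2**31 - 1)),
        )
        ct_a, spect_a, truth_a = generate_phantom(spec_aff)
        ct_u, spect_u, truth_u = generate_phantom(spec_unaff)
        assert truth_a.hybrid_class.value == cls, "coupling table out of sync"
        planar, contaminated = _degrade_planar(truth_a.findings, planar_model, rng)
        record = PatientRecord(
            id=f"PH{i:03d}",
            extremity=base.extremity,
            affected_side=str(rng.choice(["left", "right"])),
            duration_months=duration,
            contamination_flag=contaminated,
        )
        studies.append(PhantomStudy(
            record=record,
            spec=spec_aff,
            ct_affected=ct_a,
            spect_affected=spect_a,
            truth=truth_a,
            ct_unaffected=ct_u,
            spect_unaffected=spect_u,
            truth_unaffected=truth_u,
            planar_findings=planar,
            combined_findings=truth_a.findings,
        ))
    return studies
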