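"""Per-patient and per-cohort orchestration.

``run_patient`` composes the quantification chain on one study: limb and
compartment segmentation on both limbs, CT volumetry and severity grade,
HP windowing, DBF iso-contour extraction, per-region DBF/HP patterns,
TLS staging and the hybrid class.  Lymph-node and duct visibility are
reader inputs (human calls on the images), not computed quantities.

``run_cohort`` maps ``run_patient`` over synthetic studies, crosses the
planar-only and combined stage calls, and runs the statistical battery
(Kruskal-Wallis + Dunn by severity grade and stage, Mann-Whitney by
chronicity, Spearman of class vs grade/stage, linear-by-linear trends).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import stats as lstats
from .core import ImageVolume, PatientRecord
from .ct import (
    CtQuantConfig,
    VolumetryResult,
    compute_volume,
    hp_ratio,
    segment_compartments,
    segment_limb,
    volumetric_grade,
)
from .phantom import PhantomStudy
from .spect import DbfConfig, DbfResult, auto_seeds, dbf_extent, dbf_ratio, extract_dbf, split_regions
from .staging import (
    FindingsRecord,
    HybridClass,
    StageCallPair,
    StagingComparison,
    TLSRuleTable,
    TLSStage,
    compare_stagings,
    hybrid_classify,
    region_pattern,
    tls_stage,
)

logger = logging.getLogger("lymphspect")

__all__ = [
    "PipelineConfig",
    "PipelineError",
    "PatientResult",
    "CohortReport",
    "run_patient",
    "run_cohort",
]


@dataclass
class PipelineConfig:
    """All tunables of the per-patient chain in one place."""

    ct: CtQuantConfig = field(default_factory=CtQuantConfig)
    dbf: DbfConfig = field(default_factory=DbfConfig)
    rule_table: TLSRuleTable | None = None
    #: regional HP-presence threshold: HP ratio of the region's SC
    tau_hp: float = 0.05
    #: fallback policy for pattern pairs the five classes do not cover
    classify_policy: str = "strict"


class PipelineError(RuntimeError):
    """A pipeline stage failed; carries the stage name and patient id."""


@dataclass
class PatientResult:
    """Everything the chain computes for one patient."""

    patient_id: str
    volumetry: VolumetryResult
    hp_volume_cm3: float
    hp_ratio: float
    hp_ratio_by_region: dict
    dbf: DbfResult
    patterns: dict
    hybrid_class: HybridClass
    findings: FindingsRecord
    tls_combined: TLSStage
    masks: dict = field(default_factory=dict)

    def to_row(self) -> dict:
        return {
            "id": self.patient_id,
            "volume_affected_cm3": self.volumetry.volume_affected_cm3,
            "volume_unaffected_cm3": self.volumetry.volume_unaffected_cm3,
            "ct_diff_percent": self.volumetry.ct_diff_percent,
            "severity_grade": self.volumetry.severity_grade,
            "hp_volume_cm3": self.hp_volume_cm3,
            "hp_ratio": self.hp_ratio,
            "hp_ratio_proximal": self.hp_ratio_by_region["proximal"],
            "hp_ratio_distal": self.hp_ratio_by_region["distal"],
            "dbf_volume_cm3": self.dbf.dbf_volume_cm3,
            "dbf_ratio": self.dbf.dbf_ratio,
            "dbf_extent": self.dbf.extent,
            "pattern_proximal": self.patterns["proximal"].pattern,
            "pattern_distal": self.patterns["distal"].pattern,
            "hybrid_class": self.hybrid_class.value,
            "hybrid_class_imputed": self.hybrid_class.imputed,
            "tls_combined": self.tls_combined.label,
        }


def _default_seed(ct: ImageVolume) -> tuple[int, int, int]:
    """Brightest voxel — always deep tissue (bone), never air."""
    return tuple(int(i) for i in np.unravel_index(int(np.argmax(ct.voxels)), ct.shape))


def run_patient(
    ct_affected: ImageVolume,
    spect_affected: ImageVolume,
    ct_unaffected: ImageVolume,
    visibility: dict,
    patient_id: str = "anon",
    exclusion_mask: np.ndarray | None = None,
    limb_seed_affected: tuple[int, int, int] | None = None,
    limb_seed_unaffected: tuple[int, int, int] | None = None,
    cfg: PipelineConfig | None = None,
    keep_masks: bool = False,
) -> PatientResult:
    """Run the full quantification chain for one patient.

    ``visibility`` carries the reader calls: keys ``proximal_ln``,
    ``intermediate_ln``, ``ducts`` (bools).  ``exclusion_mask`` marks
    non-dermal hotspots (injection depot, nodes, ducts) to exclude from
    DBF extraction.  Stage failures re-raise as :class:`PipelineError`
    naming the stage and patient.
    """
    cfg = cfg or PipelineConfig()
    if not ct_affected.same_grid(spect_affected):
        raise PipelineError(f"[{patient_id}] CT and SPECT grids are not co-registered")

    def _stage(name, fn):
        try:
            out = fn()
        except Exception as exc:
            raise PipelineError(f"stage {name!r} failed for patient {patient_id}: {exc}") from exc
        logger.info("patient=%s stage=%s done", patient_id, name)
        return out

    comps_a = _stage("segment_affected", lambda: segment_compartments(
        ct_affected,
        segment_limb(ct_affected, limb_seed_affected or _default_seed(ct_affected), cfg.ct),
        cfg.ct))
    comps_u = _stage("segment_unaffected", lambda: segment_compartments(
        ct_unaffected,
        segment_limb(ct_unaffected, limb_seed_unaffected or _default_seed(ct_unaffected), cfg.ct),
        cfg.ct))
    volumetry = _stage("volumetry", lambda: volumetric_grade(
        compute_volume(comps_a.limb, ct_affected.spacing),
        compute_volume(comps_u.limb, ct_unaffected.spacing)))

    hp_mask, hp_cm3, ratio = _stage("hp_ratio", lambda: hp_ratio(
        ct_affected, comps_a.subcutaneous, cfg.ct))
    regions = split_regions(comps_a.limb, ct_affected.limb_axis,
                            cfg.dbf.region_split_fraction)
    hp_by_region = {}
    for name, rmask in regions.items():
        sc_r = comps_a.subcutaneous & rmask
        hp_by_region[name] = (
            hp_ratio(ct_affected, sc_r, cfg.ct)[2] if sc_r.any() else 0.0
        )

    def _dbf():
        seeds = auto_seeds(spect_affected, comps_a.subcutaneous, exclusion_mask, cfg.dbf)
        mask = extract_dbf(spect_affected, seeds, comps_a.subcutaneous,
                           exclusion_mask, cfg.dbf)
        extent, presence = dbf_extent(mask, regions, spect_affected.spacing, cfg.dbf)
        v_sc = compute_volume(comps_a.subcutaneous, ct_affected.spacing)
        return mask, DbfResult(
            dbf_volume_cm3=compute_volume(mask, spect_affected.spacing),
            dbf_ratio=dbf_ratio(mask, v_sc, spect_affected.spacing),
            extent=extent,
            proximal_present=presence["proximal"],
            distal_present=presence["distal"],
        )

    dbf_mask, dbf_res = _stage("extract_dbf", _dbf)

    findings = FindingsRecord(
        dbf_extent=dbf_res.extent,
        proximal_ln_visible=bool(visibility.get("proximal_ln", False)),
        intermediate_ln_visible=bool(visibility.get("intermediate_ln", False)),
        ducts_visible=bool(visibility.get("ducts", False)),
        reading="planar+SPECT/CT",
    )
    stage_combined = _stage("tls_stage", lambda: tls_stage(findings, cfg.rule_table))
    patterns = {
        name: region_pattern(
            {"proximal": dbf_res.proximal_present, "distal": dbf_res.distal_present}[name],
            hp_by_region[name] >= cfg.tau_hp,
            region=name,
        )
        for name in ("proximal", "distal")
    }
    hybrid = _stage("hybrid_classify", lambda: hybrid_classify(
        patterns["proximal"], patterns["distal"], policy=cfg.classify_policy))

    masks = {}
    if keep_masks:
        masks = {"compartments": comps_a, "compartments_unaffected": comps_u,
                 "hp": hp_mask, "dbf": dbf_mask, "regions": regions}
    return PatientResult(
        patient_id=patient_id,
        volumetry=volumetry,
        hp_volume_cm3=hp_cm3,
        hp_ratio=ratio,
        hp_ratio_by_region=hp_by_region,
        dbf=dbf_res,
        patterns=patterns,
        hybrid_class=hybrid,
        findings=findings,
        tls_combined=stage_combined,
        masks=masks,
    )


@dataclass
class CohortReport:
    """Cohort-level outputs: the per-patient table, the staging
    comparison, the statistical battery and distribution summaries."""

    table: pd.DataFrame
    staging: StagingComparison
    tests: dict
    summaries: dict
    class_distribution: dict

    def render_text(self) -> str:
        lines = ["=== per-patient table ==="]
        lines.append(self.table.to_string(index=False, float_format=lambda v: f"{v:.3f}"))
        lines.append("\n=== staging comparison (planar vs planar+SPECT/CT) ===")
        lines.append(self.staging.render_text())
        lines.append("\n=== hybrid class distribution ===")
        for cls, n in sorted(self.class_distribution.items()):
            lines.append(f"  Class {cls}: {n}")
        lines.append("\n=== statistical battery ===")
        for name, res in self.tests.items():
            if isinstance(res, lstats.TestResult):
                df_txt = "" if res.df is None else f", df={res.df:g}"
                lines.append(f"  {name}: {res.method} statistic={res.statistic:.4f}"
                             f"{df_txt}, p={res.p_value:.4g}")
            elif isinstance(res, pd.DataFrame):
                lines.append(f"  {name}:")
                lines.append(res.to_string(index=False))
        lines.append("\n=== numeric summaries ===")
        for name, s in self.summaries.items():
            lines.append(f"  {name}: {s.render()} [{s.display}] (n={s.n})")
        return "\n".join(lines)


def run_cohort(studies: list[PhantomStudy], cfg: PipelineConfig | None = None) -> CohortReport:
    """Quantify every study, cross the stage readings, run the battery.

    Hybrid classification uses the nearest-prototype fallback here so a
    noisy recovery of an uncovered pattern pair still yields an ordinal
    class for the correlation analyses (tagged in the table).
    """
    if len(studies) < 2:
        raise ValueError("cohort analysis needs at least 2 patients")
    cfg = cfg or PipelineConfig()
    if cfg.classify_policy == "strict":
        cfg = PipelineConfig(ct=cfg.ct, dbf=cfg.dbf, rule_table=cfg.rule_table,
                             tau_hp=cfg.tau_hp, classify_policy="nearest")

    rows = []
    pairs = []
    for study in studies:
        vis = {
            "proximal_ln": study.combined_findings.proximal_ln_visible,
            "intermediate_ln": study.combined_findings.intermediate_ln_visible,
            "ducts": study.combined_findings.ducts_visible,
        }
        res = run_patient(
            study.ct_affected, study.spect_affected, study.ct_unaffected,
            visibility=vis,
            patient_id=study.record.id,
            exclusion_mask=study.truth.exclusion_mask,
            cfg=cfg,
        )
        row = res.to_row()
        row.update({
            "class_true": study.truth.hybrid_class.value,
            "tls_true": study.truth.tls.label,
            "grade_true": study.truth.severity_grade,
            "duration_months": study.record.duration_months,
            "chronic": study.record.chronic,
            "contamination": study.record.contamination_flag,
            "tls_planar": tls_stage(study.planar_findings, cfg.rule_table).label,
        })
        rows.append(row)
        pairs.append(StageCallPair(
            subject_id=study.record.id,
            planar=row["tls_planar"],
            combined=row["tls_combined"],
            contamination=study.record.contamination_flag,
        ))
    table = pd.DataFrame(rows)
    staging = compare_stagings(pairs)

    tests: dict = {}
    summaries: dict = {}
    rank = {lab: i for i, lab in
            enumerate(("L-0", "P-1", "P-2", "P-3", "T-4", "T-5", "T-6"))}
    table["tls_rank"] = table["tls_combined"].map(rank)

    def _groups(value_col, by_col):
        grouped = [g[value_col].to_numpy() for _, g in table.groupby(by_col) if len(g)]
        return [g for g in grouped if g.size]

    for value in ("hp_ratio", "dbf_ratio"):
        by_grade = _groups(value, "severity_grade")
        if len(by_grade) >= 2:
            tests[f"{value}_by_grade"] = lstats.kruskal_wallis(by_grade)
            tests[f"{value}_by_grade_posthoc"] = lstats.dunn_bonferroni(
                by_grade, labels=[str(g) for g in sorted(table["severity_grade"].unique())])
        by_stage = _groups(value, "tls_rank")
        if len(by_stage) >= 2:
            tests[f"{value}_by_stage"] = lstats.kruskal_wallis(by_stage)
        chronic = table[table["chronic"]][value].to_numpy()
        nonchronic = table[~table["chronic"]][value].to_numpy()
        if chronic.size and nonchronic.size:
            tests[f"{value}_by_chronicity"] = lstats.mann_whitney(chronic, nonchronic)
        summaries[value] = lstats.summarize_numeric(table[value])
    summaries["duration_months"] = lstats.summarize_numeric(table["duration_months"])

    if table["hybrid_class"].nunique() >= 2:
        tests["class_vs_grade"] = lstats.spearman(table["hybrid_class"], table["severity_grade"])
        tests["class_vs_stage"] = lstats.spearman(table["hybrid_class"], table["tls_rank"])
        mild = (table["severity_grade"] <= 2).astype(int)
        ct_tab = pd.crosstab(table["hybrid_class"], mild)
        if ct_tab.shape[1] == 2:
            tests["trend_class_vs_mild_severity"] = lstats.linear_by_linear(ct_tab.to_numpy())
        chron = pd.crosstab(table["hybrid_class"], table["chronic"].astype(int))
        if chron.shape[1] == 2:
            tests["trend_class_vs_chronicity"] = lstats.linear_by_linear(chron.to_numpy())

    class_distribution = table["hybrid_class"].value_counts().to_dict()
    return CohortReport(table=table, staging=staging, tests=tests,
                        summaries=summaries, class_distribution=class_distribution)
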