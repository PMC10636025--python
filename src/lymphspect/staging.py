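"""Ordinal staging rule engines for lymphoscintigraphy.

Three rule systems live here:

* the Taiwan Lymphoscintigraphy Staging (TLS) engine — seven ordinal
  stages (normal L-0; partial obstruction P-1..P-3; total obstruction
  T-4..T-6) decided by lymph-node/duct visualization and the extent of
  dermal backflow (DBF);
* the per-region DBF/HP pattern product (four patterns) and the hybrid
  SPECT/CT Class 1-5 classifier built on the ordered
  (proximal, distal) pattern pair;
* the planar vs planar+SPECT/CT staging comparison (contingency table,
  modification rate, off-diagonal decomposition).

The TLS rule table is data: the default below is reconstructed from the
in-study stage descriptors and can be swapped wholesale.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field, replace

import numpy as np

from .core import ContingencyTable

__all__ = [
    "DBF_EXTENTS",
    "PATTERNS",
    "PATTERN_LABELS",
    "STAGE_ORDER",
    "FindingsRecord",
    "TLSStage",
    "TLSRuleTable",
    "DEFAULT_RULE_TABLE",
    "tls_stage",
    "RegionPattern",
    "region_pattern",
    "HybridClass",
    "UnclassifiablePatternError",
    "hybrid_classify",
    "classify_pattern_pair",
    "StageCallPair",
    "StagingComparison",
    "compare_stagings",
    "pairs_from_table",
]

DBF_EXTENTS = ("none", "proximal", "distal", "entire")

#: short pattern keys: first sign is DBF presence, second is HP presence
PATTERNS = ("--", "+-", "++", "-+")
PATTERN_LABELS = {
    "--": "DBF-/HP-",
    "+-": "DBF+/HP-",
    "++": "DBF+/HP+",
    "-+": "DBF-/HP+",
}
_LABEL_TO_KEY = {v: k for k, v in PATTERN_LABELS.items()}

STAGE_ORDER = ("L-0", "P-1", "P-2", "P-3", "T-4", "T-5", "T-6")
_STAGE_GROUP = {
    "L-0": "normal",
    "P-1": "partial", "P-2": "partial", "P-3": "partial",
    "T-4": "total", "T-5": "total", "T-6": "total",
}


@dataclass(frozen=True)
class FindingsRecord:
    """Structured lymphoscintigraphic observations for one reading."""

    dbf_extent: str  # none / proximal / distal / entire
    proximal_ln_visible: bool
    intermediate_ln_visible: bool
    ducts_visible: bool
    contamination_flag: bool = False
    reading: str = "planar+SPECT/CT"  # or "planar"

    def __post_init__(self) -> None:
        if self.dbf_extent not in DBF_EXTENTS:
            raise ValueError(f"dbf_extent must be one of {DBF_EXTENTS}, got {self.dbf_extent!r}")


@dataclass(frozen=True)
class TLSStage:
    """One TLS stage with its ordinal rank and obstruction group."""

    label: str

    def __post_init__(self) -> None:
        if self.label not in STAGE_ORDER:
            raise ValueError(f"unknown TLS stage {self.label!r}")

    @property
    def rank(self) -> int:
        return STAGE_ORDER.index(self.label)

    @property
    def group(self) -> str:
        return _STAGE_GROUP[self.label]


@dataclass(frozen=True)
class TLSRuleTable:
    """Swappable TLS decision table.

    The obstruction group is decided by lymph-node visualization
    (``partial`` iff a proximal or intermediate node is seen, ``total``
    otherwise); within each group the stage follows the DBF extent.
    L-0 (normal drainage) additionally requires duct visualization and,
    by default, both node stations — a partial-obstruction limb with no
    DBF but an incomplete node picture stays P-1.
    """

    partial_by_extent: dict = field(default_factory=lambda: {
        "none": "P-1", "proximal": "P-2", "distal": "P-2", "entire": "P-3",
    })
    total_by_extent: dict = field(default_factory=lambda: {
        "entire": "T-4", "proximal": "T-5", "distal": "T-5", "none": "T-6",
    })
    l0_requires_ducts: bool = True
    l0_requires_both_nodes: bool = True

    def validate(self) -> None:
        """Raise if the table is not total over the findings domain."""
        for mapping, name in ((self.partial_by_extent, "partial"),
                              (self.total_by_extent, "total")):
            missing = set(DBF_EXTENTS) - set(mapping)
            if missing:
                raise ValueError(f"{name} rule map does not cover extents {sorted(missing)}")
            bad = {v for v in mapping.values() if v not in STAGE_ORDER}
            if bad:
                raise ValueError(f"{name} rule map assigns unknown stages {sorted(bad)}")

    def stage(self, findings: FindingsRecord) -> TLSStage:
        ln_seen = findings.proximal_ln_visible or findings.intermediate_ln_visible
        if findings.dbf_extent == "none" and ln_seen:
            normal = (findings.ducts_visible if self.l0_requires_ducts else True) and (
                (findings.proximal_ln_visible and findings.intermediate_ln_visible)
                if self.l0_requires_both_nodes else True
            )
            if normal:
                return TLSStage("L-0")
        if ln_seen:
            return TLSStage(self.partial_by_extent[findings.dbf_extent])
        return TLSStage(self.total_by_extent[findings.dbf_extent])


DEFAULT_RULE_TABLE = TLSRuleTable()
DEFAULT_RULE_TABLE.validate()


def tls_stage(findings: FindingsRecord, rule_table: TLSRuleTable | None = None) -> TLSStage:
    """Stage one findings record under a (default or custom) TLS rule table."""
    table = DEFAULT_RULE_TABLE if rule_table is None else rule_table
    table.validate()
    return table.stage(findings)


# ---------------------------------------------------------------------------
# per-region DBF/HP patterns and the hybrid Class 1-5 classifier
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class RegionPattern:
    """The DBF/HP presence product for one limb region."""

    dbf_present: bool
    hp_present: bool
    region: str = ""

    @property
    def key(self) -> str:
        return ("+" if self.dbf_present else "-") + ("+" if self.hp_present else "-")

    @property
    def pattern(self) -> str:
        return PATTERN_LABELS[self.key]


def region_pattern(dbf_present: bool, hp_present: bool, region: str = "") -> RegionPattern:
    """Exact two-flag product; all four flag pairs map to distinct patterns."""
    return RegionPattern(dbf_present=bool(dbf_present), hp_present=bool(hp_present), region=region)


class UnclassifiablePatternError(ValueError):
    """The five class definitions do not cover this (proximal, distal) pair."""


@dataclass(frozen=True)
class HybridClass:
    """Ordinal hybrid SPECT/CT class (1..5); ``imputed`` marks a
    nearest-prototype fallback assignment for an uncovered pattern pair."""

    value: int
    imputed: bool = False

    def __post_init__(self) -> None:
        if self.value not in (1, 2, 3, 4, 5):
            raise ValueError(f"hybrid class must be 1..5, got {self.value}")


def _coerce_key(pattern) -> str:
    if isinstance(pattern, RegionPattern):
        return pattern.key
    if pattern in PATTERNS:
        return pattern
    if pattern in _LABEL_TO_KEY:
        return _LABEL_TO_KEY[pattern]
    raise ValueError(f"not a DBF/HP pattern: {pattern!r}")


def classify_pattern_pair(proximal_key: str, distal_key: str) -> int | None:
    """Literal class rules applied in order 1..5; None if no rule matches.

    Class 1: DBF-/HP- in the entire limb.
    Class 2: DBF+/HP- somewhere, with no DBF+/HP+ or DBF-/HP+ anywhere.
    Class 3: DBF+/HP+ somewhere, with no DBF-/HP+ anywhere.
    Class 4: coexistence of DBF+/HP+ and DBF-/HP+.
    Class 5: DBF-/HP+ in the entire limb.
    """
    pats = {proximal_key, distal_key}
    if pats == {"--"}:
        return 1
    if "+-" in pats and pats <= {"--", "+-"}:
        return 2
    if "++" in pats and "-+" not in pats:
        return 3
    if "++" in pats and "-+" in pats:
        return 4
    if pats == {"-+"}:
        return 5
    return None


def _hamming(a: str, b: str) -> int:
    return (a[0] != b[0]) + (a[1] != b[1])


def _nearest_class(proximal_key: str, distal_key: str) -> int:
    """Nearest covered ordered pair by per-region flag (Hamming) distance;
    ties resolve to the lower (milder) class."""
    best = (5, 6)  # (distance, class)
    for p, d in itertools.product(PATTERNS, repeat=2):
        cls = classify_pattern_pair(p, d)
        if cls is None:
            continue
        dist = _hamming(proximal_key, p) + _hamming(distal_key, d)
        if (dist, cls) < best:
            best = (dist, cls)
    return best[1]


def hybrid_classify(proximal, distal, policy: str = "strict") -> HybridClass:
    """Classify the ordered (proximal, distal) pattern pair into Class 1-5.

    ``policy`` controls uncovered pairs: ``strict`` raises
    :class:`UnclassifiablePatternError`; ``nearest`` assigns the closest
    covered pair's class and tags the result ``imputed``.
    """
    if policy not in ("strict", "nearest"):
        raise ValueError(f"unknown fallback policy {policy!r}")
    p, d = _coerce_key(proximal), _coerce_key(distal)
    cls = classify_pattern_pair(p, d)
    if cls is not None:
        return HybridClass(cls)
    if policy == "strict":
        raise UnclassifiablePatternError(
            f"pattern pair (proximal={PATTERN_LABELS[p]}, distal={PATTERN_LABELS[d]}) "
            "is not covered by the five class definitions"
        )
    return HybridClass(_nearest_class(p, d), imputed=True)


# ---------------------------------------------------------------------------
# planar vs planar+SPECT/CT staging comparison
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class StageCallPair:
    """Both readings for one subject: planar-only and planar+SPECT/CT."""

    subject_id: str
    planar: str
    combined: str
    contamination: bool = False

    def __post_init__(self) -> None:
        for label in (self.planar, self.combined):
            if label is not None and label not in STAGE_ORDER:
                raise ValueError(f"unknown TLS stage {label!r}")


@dataclass
class StagingComparison:
    """Cross-tabulation of the two readings with the modification rate.

    The table is oriented combined-reading rows x planar-reading columns.
    ``decomposition`` splits the off-diagonal (modified) subjects by
    obstruction-group movement from planar to combined.
    """

    table: ContingencyTable
    n_evaluable: int
    n_excluded_contamination: int
    n_modified: int
    modification_rate_percent: float
    decomposition: dict

    def render_text(self) -> str:
        lines = ["TLS stage comparison (rows: planar+SPECT/CT, columns: planar only)"]
        lines.append(self.table.to_frame().to_string())
        lines.append(
            f"evaluable N = {self.n_evaluable} "
            f"(excluded for contamination artifacts: {self.n_excluded_contamination})"
        )
        lines.append(
            f"modified stagings: {self.n_modified} "
            f"({self.modification_rate_percent:.1f}%)"
        )
        d = self.decomposition
        lines.append(
            "  within partial: {within_partial}, within total: {within_total}, "
            "partial->total: {partial_to_total}, total->partial: {total_to_partial}".format(**d)
        )
        return "\n".join(lines)


def compare_stagings(pairs: list[StageCallPair],
                     labels: tuple[str, ...] | None = None) -> StagingComparison:
    """Cross-tabulate paired stage calls, excluding contamination artifacts.

    Subjects conserve: evaluable (diagonal + off-diagonal) + excluded equals
    the input count.  ``labels`` defaults to the stages observed among the
    evaluable pairs, in TLS order.
    """
    missing = [p.subject_id for p in pairs if p.planar is None or p.combined is None]
    if missing:
        raise ValueError(f"subjects missing one reading: {missing}")
    evaluable = [p for p in pairs if not p.contamination]
    excluded = len(pairs) - len(evaluable)
    if not evaluable:
        raise ValueError("no evaluable subjects after contamination exclusion")
    if labels is None:
        seen = {p.planar for p in evaluable} | {p.combined for p in evaluable}
        labels = tuple(s for s in STAGE_ORDER if s in seen)
    idx = {s: i for i, s in enumerate(labels)}
    counts = np.zeros((len(labels), len(labels)), dtype=int)
    decomposition = {"within_partial": 0, "within_total": 0,
                     "partial_to_total": 0, "total_to_partial": 0}
    for p in evaluable:
        counts[idx[p.combined], idx[p.planar]] += 1
        if p.planar != p.combined:
            g_from, g_to = _STAGE_GROUP[p.planar], _STAGE_GROUP[p.combined]
            if g_from == g_to == "partial":
                decomposition["within_partial"] += 1
            elif g_from == g_to == "total":
                decomposition["within_total"] += 1
            elif g_from == "partial" and g_to == "total":
                decomposition["partial_to_total"] += 1
            elif g_from == "total" and g_to == "partial":
                decomposition["total_to_partial"] += 1
    table = ContingencyTable(labels=labels, counts=counts)
    n_modified = int(counts.sum() - np.trace(counts))
    rate = 100.0 * n_modified / len(evaluable)
    return StagingComparison(
        table=table,
        n_evaluable=len(evaluable),
        n_excluded_contamination=excluded,
        n_modified=n_modified,
        modification_rate_percent=rate,
        decomposition=decomposition,
    )


def pairs_from_table(table: ContingencyTable, prefix: str = "S") -> list[StageCallPair]:
    """Expand a combined-rows x planar-columns count table into stage-call
    pairs (synthetic subject ids) — the inverse of :func:`compare_stagings`."""
    pairs = []
    k = 0
    for i, combined in enumerate(table.labels):
        for j, planar in enumerate(table.labels):
            for _ in range(int(table.counts[i, j])):
                pairs.append(StageCallPair(f"{prefix}{k:03d}", planar=planar, combined=combined))
                k += 1
    return pairs
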