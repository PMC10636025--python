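import itertools

import numpy as np
import pytest

from lymphspect import (
    FindingsRecord,
    StageCallPair,
    TLSRuleTable,
    compare_stagings,
    hybrid_classify,
    region_pattern,
    tls_stage,
)
from lymphspect.datasets import reference_staging_pairs, reference_staging_table
from lymphspect.staging import (
    DBF_EXTENTS,
    PATTERNS,
    STAGE_ORDER,
    UnclassifiablePatternError,
    classify_pattern_pair,
    pairs_from_table,
)


def _findings(extent="none", prox=True, inter=False, ducts=True):
    return FindingsRecord(dbf_extent=extent, proximal_ln_visible=prox,
                          intermediate_ln_visible=inter, ducts_visible=ducts)


class TestTlsStage:
    @pytest.mark.parametrize("findings,expected", [
        # no DBF, proximal node and ducts seen, incomplete node picture -> P-1
        (_findings("none", prox=True, inter=False, ducts=True), "P-1"),
        # distal DBF with a node seen -> P-2
        (_findings("distal", prox=True), "P-2"),
        (_findings("proximal", prox=True), "P-2"),
        # entire-limb DBF with nodes -> P-3
        (_findings("entire", prox=True, inter=True), "P-3"),
        # no nodes: total obstruction; entire DBF -> T-4
        (_findings("entire", prox=False, inter=False, ducts=False), "T-4"),
        (_findings("distal", prox=False, inter=False, ducts=False), "T-5"),
        # HP-without-DBF late disease: nothing visualized -> T-6
        (_findings("none", prox=False, inter=False, ducts=False), "T-6"),
        # full normal picture -> L-0
        (_findings("none", prox=True, inter=True, ducts=True), "L-0"),
    ])
    def test_default_rule_table(self, findings, expected):
        assert tls_stage(findings).label == expected

    def test_total_over_findings_domain(self):
        """Every extent x node x duct combination yields exactly one stage."""
        for extent, prox, inter, ducts in itertools.product(
                DBF_EXTENTS, (False, True), (False, True), (False, True)):
            stage = tls_stage(_findings(extent, prox, inter, ducts))
            assert stage.label in STAGE_ORDER

    def test_stage_rank_and_group(self):
        stage = tls_stage(_findings("none", prox=False, ducts=False))
        assert stage.group == "total" and stage.rank == 6

    def test_incomplete_rule_table_rejected(self):
        bad = TLSRuleTable(partial_by_extent={"none": "P-1"})
        with pytest.raises(ValueError, match="cover"):
            tls_stage(_findings(), rule_table=bad)

    def test_swapped_rule_table_is_honoured(self):
        # a reading convention where single-region DBF under total
        # obstruction is T-4 (per-patient variants exist in practice)
        table = TLSRuleTable(total_by_extent={
            "entire": "T-4", "proximal": "T-4", "distal": "T-4", "none": "T-6"})
        stage = tls_stage(_findings("distal", prox=False, ducts=False), rule_table=table)
        assert stage.label == "T-4"


class TestRegionPattern:
    def test_all_four_flag_pairs_distinct(self):
        patterns = {region_pattern(d, h).pattern for d in (False, True) for h in (False, True)}
        assert patterns == {"DBF-/HP-", "DBF+/HP-", "DBF+/HP+", "DBF-/HP+"}

    def test_label_semantics(self):
        assert region_pattern(True, True).pattern == "DBF+/HP+"
        assert region_pattern(False, False).pattern == "DBF-/HP-"


# hand-derived decision table over ordered (proximal, distal) short keys;
# independently re-derived from the five class definitions, not from the code
EXPECTED_CLASSES = {
    ("--", "--"): 1,
    ("+-", "--"): 2, ("--", "+-"): 2, ("+-", "+-"): 2,
    ("++", "--"): 3, ("--", "++"): 3, ("++", "+-"): 3, ("+-", "++"): 3, ("++", "++"): 3,
    ("++", "-+"): 4, ("-+", "++"): 4,
    ("-+", "-+"): 5,
}
EXPECTED_UNCOVERED = {("+-", "-+"), ("-+", "+-"), ("--", "-+"), ("-+", "--")}


class TestHybridClassify:
    def test_full_enumeration_matches_decision_table(self):
        got_covered, got_uncovered = {}, set()
        for pair in itertools.product(PATTERNS, repeat=2):
            cls = classify_pattern_pair(*pair)
            if cls is None:
                got_uncovered.add(pair)
            else:
                got_covered[pair] = cls
        assert got_covered == EXPECTED_CLASSES
        assert got_uncovered == EXPECTED_UNCOVERED

    @pytest.mark.parametrize("prox,dist,cls", [
        ("DBF-/HP-", "DBF-/HP-", 1),   # nothing anywhere
        ("DBF-/HP-", "DBF+/HP-", 2),   # distal backflow, no fibrosis
        ("DBF+/HP+", "DBF+/HP+", 3),   # backflow with fibrosis, both regions
        ("DBF-/HP+", "DBF+/HP+", 4),   # mixed: distal active, proximal burnt-out
        ("DBF-/HP+", "DBF-/HP+", 5),   # fibrosis only, entire limb
    ])
    def test_representative_cases(self, prox, dist, cls):
        assert hybrid_classify(prox, dist).value == cls

    def test_strict_policy_raises_on_uncovered(self):
        for prox, dist in EXPECTED_UNCOVERED:
            with pytest.raises(UnclassifiablePatternError):
                hybrid_classify(prox, dist, policy="strict")

    def test_nearest_policy_imputes_all_uncovered(self):
        for prox, dist in EXPECTED_UNCOVERED:
            out = hybrid_classify(prox, dist, policy="nearest")
            assert out.imputed and 1 <= out.value <= 5

    def test_covered_pairs_never_imputed(self):
        for (prox, dist), cls in EXPECTED_CLASSES.items():
            out = hybrid_classify(prox, dist, policy="nearest")
            assert out.value == cls and not out.imputed

    def test_region_symmetry_of_covered_pairs(self):
        for (prox, dist), cls in EXPECTED_CLASSES.items():
            if (dist, prox) in EXPECTED_CLASSES:
                assert EXPECTED_CLASSES[(dist, prox)] == cls

    def test_unknown_policy_rejected(self):
        with pytest.raises(ValueError, match="policy"):
            hybrid_classify("--", "--", policy="fuzzy")


class TestCompareStagings:
    def test_reference_cohort_modification_rate(self):
        comparison = compare_stagings(reference_staging_pairs())
        assert comparison.n_evaluable == 39
        assert comparison.n_excluded_contamination == 2
        assert comparison.n_modified == 6
        assert comparison.modification_rate_percent == pytest.approx(15.4, abs=0.05)
        assert comparison.decomposition == {
            "within_partial": 2, "within_total": 0,
            "partial_to_total": 0, "total_to_partial": 4,
        }

    def test_reference_table_reconstructed_exactly(self):
        comparison = compare_stagings(reference_staging_pairs())
        ref = reference_staging_table()
        assert comparison.table.labels == ref.labels
        np.testing.assert_array_equal(comparison.table.counts, ref.counts)

    def test_pairs_from_table_round_trip(self):
        ref = reference_staging_table()
        comparison = compare_stagings(pairs_from_table(ref))
        np.testing.assert_array_equal(comparison.table.counts, ref.counts)

    def test_identical_readings_rate_zero(self):
        pairs = [StageCallPair(f"s{i}", planar="P-2", combined="P-2") for i in range(10)]
        comparison = compare_stagings(pairs)
        assert comparison.n_modified == 0
        assert comparison.modification_rate_percent == 0.0
        assert np.trace(comparison.table.counts) == 10

    def test_subject_conservation(self):
        pairs = reference_staging_pairs()
        comparison = compare_stagings(pairs)
        assert comparison.table.total + comparison.n_excluded_contamination == len(pairs)

    def test_contaminated_partial_to_total_pairs_vanish(self):
        """With the 2 artifact subjects included as evaluable, the cohort
        shows 8 modifications incl. 2 partial->total; flagged, they leave
        both the table and the rate."""
        pairs = reference_staging_pairs()
        unflagged = [StageCallPair(p.subject_id, p.planar, p.combined, False) for p in pairs]
        with_artifacts = compare_stagings(unflagged)
        assert with_artifacts.n_modified == 8
        assert with_artifacts.decomposition["partial_to_total"] == 2
        clean = compare_stagings(pairs)
        assert clean.n_modified == 6
        assert clean.decomposition["partial_to_total"] == 0

    def test_missing_reading_lists_ids(self):
        pairs = [StageCallPair("ok", "P-1", "P-1"),
                 StageCallPair("gone", "P-1", None)]
        with pytest.raises(ValueError, match="gone"):
            compare_stagings(pairs)
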