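"""The four-rule EC-assignment cascade and its evidence filters."""

import itertools

import pytest

from conftest import mk_hit
from cazymeta.annotation import CazymeAnnotation, EcSource
from cazymeta.ec import assign_ec, filter_cazydb, filter_dbcansub
from cazymeta.io_formats import AlignmentHit, KoAnnotation, KoSource, ReferenceMaps

MAPS = ReferenceMaps(
    family_ec_map={"GH13": frozenset({"3.2.1.1", "3.2.1.133"}), "GH16": frozenset({"3.2.1.39"})},
    substrate_map={},
)
ANN = CazymeAnnotation("g1", frozenset({"GH13"}))


def alignment(ec=frozenset(), family="GH13", evalue=1e-150, pident=80.0, qcov=90.0):
    return AlignmentHit("g1", "ref", pident, qcov, evalue, 500.0,
                        subject_ec=frozenset(ec), subject_family=family)


def ko(source, ecs):
    return KoAnnotation("g1", "K00001", frozenset(ecs), source)


class TestFilters:
    def test_dbcansub_uses_hmm_criteria(self):
        rejected = mk_hit(i_evalue=1e-17)
        kept = mk_hit(i_evalue=1e-19, hmm_from=1, hmm_to=40, hmm_length=100)
        assert filter_dbcansub([rejected]) == []
        assert filter_dbcansub([kept]) == [kept]
        assert filter_dbcansub([]) == []

    def test_dbcansub_resolves_overlaps_per_gene(self):
        a = mk_hit(family="GH13_1", ali_from=1, ali_to=100, i_evalue=1e-30)
        b = mk_hit(family="GH13_2", ali_from=40, ali_to=110, i_evalue=1e-20)
        assert filter_dbcansub([a, b]) == [a]

    def test_cazydb_boundaries(self):
        at_thresholds = alignment(evalue=1e-103, pident=35.0, qcov=70.0)
        assert filter_cazydb([at_thresholds]) == [at_thresholds]  # inclusive pid/qcov
        assert filter_cazydb([alignment(evalue=1e-102)]) == []  # strict E
        assert filter_cazydb([alignment(pident=34.9)]) == []
        assert filter_cazydb([alignment(qcov=69.9)]) == []
        assert filter_cazydb([]) == []


class TestCascade:
    def test_rule1_beats_conflicting_rule3_evidence(self):
        sub = mk_hit(family="GH13_sub1", ec_numbers=frozenset({"3.2.1.39"}))
        conflicting = alignment(ec={"3.2.1.133"})
        out = assign_ec(ANN, [sub], [], [conflicting], [], MAPS)
        assert out.ec_numbers == {"3.2.1.39"}
        assert out.ec_source is EcSource.RULE1

    def test_rule2_requires_family_agreement(self):
        agreed = assign_ec(ANN, [], [ko(KoSource.DRAM, {"3.2.1.1"})], [], [], MAPS)
        assert agreed.ec_numbers == {"3.2.1.1"}
        assert agreed.ec_source is EcSource.RULE2
        # an EC outside the family's curated list does not fire rule 2
        foreign = assign_ec(ANN, [], [ko(KoSource.DRAM, {"1.1.1.1"})], [], [], MAPS)
        assert foreign.ec_source is EcSource.NONE

    def test_rule3_fires_when_dram_disagrees(self):
        out = assign_ec(
            ANN,
            [],
            [ko(KoSource.DRAM, {"1.1.1.1"})],
            [alignment(ec={"3.2.1.133"})],
            [],
            MAPS,
        )
        assert out.ec_numbers == {"3.2.1.133"}
        assert out.ec_source is EcSource.RULE3

    def test_rule3_requires_same_family(self):
        other_family = alignment(ec={"3.2.1.39"}, family="GH16")
        out = assign_ec(ANN, [], [], [other_family], [], MAPS)
        assert out.ec_source is EcSource.NONE

    def test_all_empty_evidence_yields_none(self):
        out = assign_ec(ANN, [], [], [], [], MAPS)
        assert out.ec_numbers == frozenset()
        assert out.ec_source is EcSource.NONE

    def test_precedence_over_all_sixteen_evidence_patterns(self):
        """For every presence pattern of rule-1..4 evidence the lowest-
        numbered present rule fires."""
        evidence = {
            1: [mk_hit(family="GH13_sub1", ec_numbers=frozenset({"3.2.1.39"}))],
            2: [ko(KoSource.DRAM, {"3.2.1.1"})],
            3: [alignment(ec={"3.2.1.133"})],
            4: [ko(KoSource.KEGG_BLAST, {"3.2.1.1"})],
        }
        for pattern in itertools.product([False, True], repeat=4):
            present = [r for r, on in zip((1, 2, 3, 4), pattern) if on]
            out = assign_ec(
                ANN,
                evidence[1] if 1 in present else [],
                evidence[2] if 2 in present else [],
                evidence[3] if 3 in present else [],
                evidence[4] if 4 in present else [],
                MAPS,
            )
            expected = EcSource(f"RULE{min(present)}") if present else EcSource.NONE
            assert out.ec_source is expected, pattern

    def test_never_invents_an_ec(self):
        sub = mk_hit(family="GH13_sub1", ec_numbers=frozenset({"3.2.1.39", "3.2.1.4"}))
        out = assign_ec(ANN, [sub], [ko(KoSource.DRAM, {"3.2.1.1"})],
                        [alignment(ec={"3.2.1.133"})], [], MAPS)
        evidence_union = {"3.2.1.39", "3.2.1.4", "3.2.1.1", "3.2.1.133"}
        assert out.ec_numbers <= evidence_union

    def test_result_is_order_independent(self):
        hits = [
            alignment(ec={"3.2.1.1"}),
            alignment(ec={"3.2.1.133"}),
        ]
        fwd = assign_ec(ANN, [], [], hits, [], MAPS)
        rev = assign_ec(ANN, [], [], hits[::-1], [], MAPS)
        assert fwd.ec_numbers == rev.ec_numbers == {"3.2.1.1", "3.2.1.133"}
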