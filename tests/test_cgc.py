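"""Signature-gene classification, cluster detection and substrate calls."""

import itertools

import numpy as np
import pytest

from conftest import mk_hit
from cazymeta.annotation import CazymeAnnotation, EcSource
from cazymeta.cgc import (
    classify_signature,
    cluster_spans,
    count_gene_pairs,
    find_cgcs,
    predict_cgc_substrate_homology,
    predict_cgc_substrate_voting,
    CGC,
)
from cazymeta.io_formats import AlignmentHit, GeneRecord, PulEntry, ReferenceMaps, Role

CAZ, TC, TF, STP, NULL = Role.CAZYME, Role.TRANSPORTER, Role.TF, Role.STP, Role.NULL


def genes_from_roles(roles, contig="c1"):
    return [
        GeneRecord(f"{contig}_g{i}", contig, "m1", i, 1 + 1000 * i, 900 + 1000 * i, "+", role=r)
        for i, r in enumerate(roles)
    ]


def oracle_spans(roles, max_gap=2):
    """Independent formulation: connected components of the pairwise
    <=max_gap-intervening-genes graph over signature positions, kept when
    the component holds a CAZyme and another signature role."""
    sig = [i for i, r in enumerate(roles) if r is not NULL]
    comps = []
    seen = set()
    for s in sig:
        if s in seen:
            continue
        comp, queue = {s}, [s]
        while queue:
            u = queue.pop()
            for v in sig:
                if v not in comp and abs(v - u) - 1 <= max_gap:
                    comp.add(v)
                    queue.append(v)
        seen |= comp
        comps.append(sorted(comp))
    out = []
    for comp in comps:
        rset = {roles[i] for i in comp}
        if CAZ in rset and rset & {TC, TF, STP}:
            out.append((comp[0], comp[-1]))
    return sorted(out)


class TestClassifySignature:
    def test_precedence_and_null(self):
        genes = [
            GeneRecord("g1", "c1", "m1", 0, 1, 900, "+"),
            GeneRecord("g2", "c1", "m1", 1, 1000, 1900, "+"),
            GeneRecord("g3", "c1", "m1", 2, 2000, 2900, "+"),
        ]
        tf_hits = [mk_hit(gene_id="g1", i_evalue=1e-10)]
        tcdb = [AlignmentHit("g2", "t1", 50.0, 80.0, 1e-20, 100.0)]
        out = classify_signature(genes, tf_hits, [], tcdb, [], cazyme_ids={"g1"})
        assert [g.role for g in out] == [CAZ, TC, NULL]  # CAZyme outranks TF


class TestFindCgcs:
    @pytest.mark.parametrize(
        "roles, expected_spans",
        [
            ([CAZ, NULL, NULL, TC], [(0, 3)]),  # two intervening genes: chained
            ([CAZ, NULL, NULL, NULL, TC], []),  # three intervening: broken
            ([CAZ, CAZ], []),  # no other signature role
            ([TF, CAZ, NULL, STP], [(0, 3)]),
            ([NULL, CAZ, TC, NULL, NULL, NULL, CAZ, TF, NULL], [(1, 2), (6, 7)]),
        ],
    )
    def test_gap_rule_examples(self, roles, expected_spans):
        cgcs = find_cgcs(genes_from_roles(roles))
        assert [(c.start_index, c.end_index) for c in cgcs] == expected_spans

    def test_unsorted_input_rejected(self):
        genes = genes_from_roles([CAZ, TC])[::-1]
        with pytest.raises(ValueError):
            find_cgcs(genes)

    def test_members_span_includes_interior_nulls(self):
        (c,) = find_cgcs(genes_from_roles([CAZ, NULL, TC]))
        assert [r for _, r in c.members] == [CAZ, NULL, TC]

    def test_matches_component_oracle_on_random_strings(self):
        rng = np.random.default_rng(3)
        alphabet = [CAZ, TC, TF, STP, NULL, NULL]
        for _ in range(500):
            roles = [alphabet[i] for i in rng.integers(0, len(alphabet), size=rng.integers(1, 13))]
            assert sorted(cluster_spans(roles)) == oracle_spans(roles)

    def test_clusters_are_disjoint(self):
        rng = np.random.default_rng(4)
        alphabet = [CAZ, TC, NULL]
        for _ in range(200):
            roles = [alphabet[i] for i in rng.integers(0, 3, size=12)]
            spans = cluster_spans(roles)
            for (a1, b1), (a2, b2) in itertools.combinations(spans, 2):
                assert b1 < a2 or b2 < a1


def make_cgc(roles=(CAZ, CAZ, TC), contig="c1"):
    members = tuple((f"{contig}_g{i}", r) for i, r in enumerate(roles))
    return CGC("cgc1", contig, 0, len(roles) - 1, members)


def pul_maps():
    return ReferenceMaps(
        family_ec_map={},
        substrate_map={},
        pul_db={
            "PUL1": PulEntry("PUL1", "xylan", (("p1_caz", CAZ), ("p1_tc", TC))),
            "PUL2": PulEntry("PUL2", "pectin", (("p2_caz", CAZ), ("p2_tc", TC))),
        },
    )


def pul_hit(query, subject, bitscore, evalue=1e-150):
    return AlignmentHit(query, subject, 50.0, 90.0, evalue, bitscore)


class TestHomologySubstrate:
    def test_eligibility_beats_raw_score(self):
        cgc = make_cgc()
        hits = [
            pul_hit("c1_g0", "p1_caz", 150.0),
            pul_hit("c1_g2", "p1_tc", 150.0),
            pul_hit("c1_g1", "p2_caz", 350.0),  # higher sum but CAZyme-only match
        ]
        out = predict_cgc_substrate_homology(cgc, hits, pul_maps())
        assert out == ("xylan", "PUL1", 300.0)

    def test_no_hits_under_threshold_gives_none(self):
        cgc = make_cgc()
        hits = [pul_hit("c1_g0", "p1_caz", 500.0, evalue=1e-50)]
        assert predict_cgc_substrate_homology(cgc, hits, pul_maps()) is None

    def test_best_hit_per_query_pul_pair_only(self):
        cgc = make_cgc()
        hits = [
            pul_hit("c1_g0", "p1_caz", 100.0),
            pul_hit("c1_g0", "p1_caz", 180.0),  # second HSP must not add up
            pul_hit("c1_g2", "p1_tc", 20.0),
        ]
        out = predict_cgc_substrate_homology(cgc, hits, pul_maps())
        assert out == ("xylan", "PUL1", 200.0)

    def test_tie_breaks_on_pul_id(self):
        cgc = make_cgc()
        hits = [
            pul_hit("c1_g0", "p1_caz", 100.0),
            pul_hit("c1_g2", "p1_tc", 100.0),
            pul_hit("c1_g0", "p2_caz", 100.0),
            pul_hit("c1_g2", "p2_tc", 100.0),
        ]
        out = predict_cgc_substrate_homology(cgc, hits, pul_maps())
        assert out[1] == "PUL1"

    def test_foreign_query_rejected(self):
        with pytest.raises(ValueError):
            predict_cgc_substrate_homology(make_cgc(), [pul_hit("other", "p1_caz", 10.0)], pul_maps())


def voting_annotations(substrate_sets):
    out = {}
    for i, subs in enumerate(substrate_sets):
        ecs = frozenset({"3.2.1.1"}) if subs else frozenset()
        out[f"c1_g{i}"] = CazymeAnnotation(
            f"c1_g{i}",
            frozenset({"GH13"}),
            ecs,
            EcSource.RULE1 if ecs else EcSource.NONE,
            frozenset(subs),
        )
    return out


class TestVotingSubstrate:
    def test_majority_wins(self):
        cgc = make_cgc((CAZ, CAZ, TC))
        anns = voting_annotations([{"xylan"}, {"xylan"}, {"pectin"}])
        assert predict_cgc_substrate_voting(cgc, anns) == (("xylan",), 2)

    def test_single_votes_fall_below_floor(self):
        cgc = make_cgc((CAZ, TC))
        anns = voting_annotations([{"xylan"}, {"pectin"}])
        assert predict_cgc_substrate_voting(cgc, anns) is None

    def test_ties_return_all_cowinners(self):
        cgc = make_cgc((CAZ, CAZ, CAZ, TC))
        anns = voting_annotations([{"xylan"}, {"xylan"}, {"pectin"}, {"pectin"}])
        assert predict_cgc_substrate_voting(cgc, anns) == (("pectin", "xylan"), 2)

    def test_matches_brute_force_tally(self):
        rng = np.random.default_rng(9)
        substrates = ["s1", "s2", "s3", "s4"]
        for _ in range(300):
            n = int(rng.integers(1, 9))
            sets = [
                set(rng.choice(substrates, size=rng.integers(0, 5), replace=False))
                for _ in range(n)
            ]
            roles = [CAZ] * n + [TC]
            cgc = make_cgc(tuple(roles))
            anns = voting_annotations(sets + [set()])
            out = predict_cgc_substrate_voting(cgc, anns)
            tally = {}
            for s in sets:
                for sub in s:
                    tally[sub] = tally.get(sub, 0) + 1
            if not tally or max(tally.values()) < 2:
                assert out is None
            else:
                top = max(tally.values())
                assert out == (tuple(sorted(k for k, v in tally.items() if v == top)), top)


class TestGenePairs:
    def test_adjacent_pair_counts_once(self):
        cgc = make_cgc((CAZ, TC, NULL))
        anns = {
            "c1_g0": CazymeAnnotation("c1_g0", frozenset({"susD"})),
            "c1_g1": CazymeAnnotation("c1_g1", frozenset({"susC"})),
        }
        assert count_gene_pairs([cgc], anns, ("susC", "susD")) == 1

    def test_separated_genes_do_not_count(self):
        cgc = make_cgc((CAZ, NULL, TC))
        anns = {
            "c1_g0": CazymeAnnotation("c1_g0", frozenset({"susD"})),
            "c1_g2": CazymeAnnotation("c1_g2", frozenset({"susC"})),
        }
        assert count_gene_pairs([cgc], anns, ("susC", "susD")) == 0

    def test_empty_cluster_list(self):
        assert count_gene_pairs([], {}, ("susC", "susD")) == 0
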