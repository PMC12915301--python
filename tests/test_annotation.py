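"""Domain-hit filtering and overlap resolution."""

import numpy as np
import pytest

from conftest import mk_hit
from cazymeta.annotation import annotate_genes, filter_hits, resolve_overlaps


def brute_force_resolution(hits):
    """Exhaustive oracle: among all subsets satisfying the pairwise
    <=50%-overlap constraint, pick the one chosen by the greedy priority
    order applied globally (lexicographically maximal inclusion over
    priority-sorted hits)."""

    def length(h):
        return h.ali_to - h.ali_from + 1

    def compatible(a, b):
        ov = max(0, min(a.ali_to, b.ali_to) - max(a.ali_from, b.ali_from) + 1)
        return ov <= 0.5 * min(length(a), length(b))

    ranked = sorted(hits, key=lambda h: (h.i_evalue, -length(h), h.family, h.ali_from))
    n = len(ranked)
    best_bits, best_subset = None, []
    for mask in range(1 << n):
        subset = [ranked[i] for i in range(n) if mask >> i & 1]
        if all(compatible(a, b) for i, a in enumerate(subset) for b in subset[i + 1 :]):
            bits = tuple(mask >> i & 1 for i in range(n))
            if best_bits is None or bits > best_bits:
                best_bits, best_subset = bits, subset
    return sorted(best_subset, key=lambda h: (h.ali_from, h.ali_to, h.family))


def random_instance(rng, n_max=6):
    hits = []
    for _ in range(int(rng.integers(1, n_max + 1))):
        start = int(rng.integers(1, 150))
        length = int(rng.integers(1, 121))
        hits.append(
            mk_hit(
                family=f"GH{rng.integers(1, 4)}",
                ali_from=start,
                ali_to=start + length - 1,
                i_evalue=float(10.0 ** -rng.integers(1, 41)),
            )
        )
    return hits


class TestFilterHits:
    def test_evalue_boundary_is_strict(self):
        at = mk_hit(i_evalue=1e-18)
        below = mk_hit(i_evalue=9.99e-19)
        assert filter_hits([at]) == []
        assert filter_hits([below]) == [below]

    def test_coverage_boundary_is_inclusive(self):
        at = mk_hit(hmm_from=1, hmm_to=35, hmm_length=100, i_evalue=1e-20)
        under = mk_hit(hmm_from=1, hmm_to=34, hmm_length=100, i_evalue=1e-20)
        assert filter_hits([at]) == [at]
        assert filter_hits([under]) == []

    def test_empty_input(self):
        assert filter_hits([]) == []


class TestResolveOverlaps:
    def test_majority_overlap_keeps_better_evalue(self):
        a = mk_hit(family="GH1", ali_from=1, ali_to=100, i_evalue=1e-30)
        b = mk_hit(family="GH2", ali_from=50, ali_to=150, i_evalue=1e-20)
        # overlap 51 aa > 50% of the shorter (100 aa) alignment
        assert resolve_overlaps([a, b]) == [a]

    def test_disjoint_hits_both_kept(self):
        a = mk_hit(family="GH1", ali_from=1, ali_to=100)
        b = mk_hit(family="GH2", ali_from=101, ali_to=200)
        assert resolve_overlaps([a, b]) == [a, b]

    def test_exactly_half_overlap_keeps_both(self):
        a = mk_hit(family="GH1", ali_from=1, ali_to=100, i_evalue=1e-30)
        b = mk_hit(family="GH2", ali_from=51, ali_to=150, i_evalue=1e-20)
        # overlap 50 aa == 50% of shorter: strictly-more-than rule keeps both
        assert resolve_overlaps([a, b]) == [a, b]

    def test_mixed_gene_ids_rejected(self):
        with pytest.raises(ValueError):
            resolve_overlaps([mk_hit(gene_id="g1"), mk_hit(gene_id="g2")])

    def test_idempotent(self):
        rng = np.random.default_rng(42)
        for _ in range(50):
            once = resolve_overlaps(random_instance(rng))
            assert resolve_overlaps(once) == once

    def test_matches_exhaustive_oracle(self):
        rng = np.random.default_rng(7)
        for _ in range(300):
            hits = random_instance(rng)
            assert resolve_overlaps(hits) == brute_force_resolution(hits)


class TestAnnotateGenes:
    def test_multi_family_gene_collects_both_families(self):
        hits = [
            mk_hit(family="GH13", ali_from=1, ali_to=100, i_evalue=1e-30),
            mk_hit(family="CBM48", ali_from=150, ali_to=220, i_evalue=1e-25),
        ]
        anns = annotate_genes(hits)
        assert anns["g1"].families == {"GH13", "CBM48"}
        assert anns["g1"].ec_numbers == frozenset()

    def test_gene_failing_coverage_absent_from_output(self):
        hit = mk_hit(hmm_from=1, hmm_to=20, hmm_length=100, i_evalue=1e-30)
        assert annotate_genes([hit]) == {}

    def test_empty_input(self):
        assert annotate_genes([]) == {}

    def test_filter_before_resolution_matters(self):
        # X has the best E-value but fails coverage; filtering first keeps Y,
        # resolving first would let X evict Y before being filtered away.
        x = mk_hit(family="GH1", hmm_from=1, hmm_to=20, hmm_length=100,
                   ali_from=1, ali_to=100, i_evalue=1e-40)
        y = mk_hit(family="GH2", hmm_from=1, hmm_to=80, hmm_length=100,
                   ali_from=10, ali_to=90, i_evalue=1e-20)
        anns = annotate_genes([x, y])
        assert anns["g1"].families == {"GH2"}
        swapped = resolve_overlaps([x, y])  # resolution without filtering
        assert filter_hits(swapped) == []  # the swapped order loses the gene
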