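"""Diversity, dissimilarity, rank statistics and expressing fractions."""

import itertools
import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.spatial.distance import braycurtis as scipy_braycurtis
from scipy.special import comb

from cazymeta.ecology import (
    bray_curtis,
    inverse_simpson,
    rank_sum_compare,
    richness_partition,
    spearman,
)

abundances = st.lists(
    st.floats(min_value=0, max_value=1e6, allow_nan=False), min_size=2, max_size=20
)


class TestRichnessPartition:
    def test_overlap_example(self):
        assert richness_partition({"GH13", "GH16"}, {"GH13", "GH5"}) == (1, 1, 1)

    def test_identical_sets(self):
        s = {f"GH{i}" for i in range(7)}
        assert richness_partition(s, set(s)) == (0, 0, 7)

    def test_one_empty_habitat_orientation(self):
        assert richness_partition(set(), {"GH1", "GH2"}) == (0, 2, 0)
        assert richness_partition({"GH1", "GH2"}, set()) == (2, 0, 0)


class TestInverseSimpson:
    def test_uniform_vector_gives_richness(self):
        assert inverse_simpson([1, 1, 1, 1]) == pytest.approx(4.0)

    def test_single_taxon(self):
        assert inverse_simpson([7]) == pytest.approx(1.0)

    def test_worked_example(self):
        assert inverse_simpson([9, 1]) == pytest.approx(1 / 0.82, rel=1e-9)

    def test_all_zero_is_an_error(self):
        with pytest.raises(ValueError):
            inverse_simpson([0, 0])

    @settings(derandomize=True, max_examples=100)
    @given(abundances.filter(lambda x: sum(x) > 0))
    def test_permutation_invariant_and_bounded_by_uniform(self, x):
        assert inverse_simpson(x) == pytest.approx(inverse_simpson(x[::-1]))
        assert inverse_simpson(x) <= len(x) + 1e-9


class TestBrayCurtis:
    def test_identical_vectors(self):
        assert bray_curtis([1, 2, 3], [1, 2, 3]) == 0.0

    def test_disjoint_supports(self):
        assert bray_curtis([1, 0], [0, 2]) == pytest.approx(1.0)

    def test_worked_example(self):
        assert bray_curtis([1, 2], [2, 1]) == pytest.approx(2 / 6)

    def test_length_mismatch(self):
        with pytest.raises(ValueError):
            bray_curtis([1], [1, 2])

    @settings(derandomize=True, max_examples=100)
    @given(abundances, abundances)
    def test_symmetric_bounded_and_matches_scipy(self, x, y):
        n = min(len(x), len(y))
        x, y = x[:n], y[:n]
        if sum(x) + sum(y) == 0:
            return
        d = bray_curtis(x, y)
        assert d == pytest.approx(bray_curtis(y, x))
        assert 0 <= d <= 1
        assert d == pytest.approx(scipy_braycurtis(x, y), abs=1e-12)


class TestSpearman:
    def test_monotone_vectors(self):
        rho, _ = spearman([1, 2, 3, 4], [10, 20, 30, 40])
        assert rho == pytest.approx(1.0)
        rho, _ = spearman([1, 2, 3, 4], [40, 30, 20, 10])
        assert rho == pytest.approx(-1.0)

    def test_worked_four_point_example(self):
        rho, p = spearman([1, 2, 3, 4], [1, 3, 2, 4])
        assert rho == pytest.approx(0.8)
        assert 0 < p < 1

    def test_constant_vector_is_an_error(self):
        with pytest.raises(ValueError):
            spearman([1, 1, 1], [1, 2, 3])


def exact_rank_sum_p(a, b):
    """Permutation oracle: enumerate all group-label assignments of the
    pooled tie-free sample and tally U values as or more extreme."""
    pooled = sorted(a + b)
    ranks = {v: i + 1 for i, v in enumerate(pooled)}
    n1, n2 = len(a), len(b)
    u_obs = sum(ranks[v] for v in a) - n1 * (n1 + 1) / 2
    us = []
    for combo in itertools.combinations(range(n1 + n2), n1):
        r = sum(c + 1 for c in combo)
        us.append(r - n1 * (n1 + 1) / 2)
    total = comb(n1 + n2, n1, exact=True)
    p_le = sum(1 for u in us if u <= u_obs) / total
    p_ge = sum(1 for u in us if u >= u_obs) / total
    return min(1.0, 2 * min(p_le, p_ge))


class TestRankSum:
    def test_identical_groups_give_p_near_one(self):
        _, p = rank_sum_compare([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert p > 0.9

    def test_fully_separated_groups_exact_p(self):
        u, p = rank_sum_compare([1, 2, 3, 4, 5], [10, 11, 12, 13, 14])
        assert u in (0.0, 25.0)
        assert p == pytest.approx(2 / 252, rel=1e-9)

    def test_single_element_groups(self):
        _, p = rank_sum_compare([1.0], [2.0])
        assert p == pytest.approx(1.0)

    def test_empty_group_is_an_error(self):
        with pytest.raises(ValueError):
            rank_sum_compare([], [1.0])

    def test_matches_permutation_enumeration(self):
        rng = np.random.default_rng(5)
        for _ in range(40):
            n1, n2 = int(rng.integers(1, 7)), int(rng.integers(1, 7))
            pooled = rng.permutation(np.arange(1.0, n1 + n2 + 1))
            a, b = list(pooled[:n1]), list(pooled[n1:])
            _, p = rank_sum_compare(a, b)
            assert p == pytest.approx(exact_rank_sum_p(a, b), rel=1e-9)
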