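"""Triangular-fuzzy three-way decision model: information difference,
fuzzy-number summaries, similarity, thresholds and region partitions."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from siteadapt import (
    CostMatrix,
    TriangularFuzzyNumber,
    delta_level_classes,
    information_difference,
    membership_probability,
    partition_regions,
    tf_similarity,
    thresholds_from_costs,
    triage,
    triangular_fuzzy_number,
)
from siteadapt.fuzzy3wd import minmax_scale_attributes, similarity_matrix

unit = st.floats(min_value=0.0, max_value=1.0, allow_nan=False)


class TestInformationDifference:
    def test_equal_values_give_zero(self):
        ID = information_difference(np.array([0.4, 0.4, 0.0, 0.0]))
        assert ID[0, 1] == 0.0
        assert ID[2, 3] == 0.0  # 0/0 convention: ratio defined as 0

    def test_extreme_pair_reaches_one(self):
        ID = information_difference(np.array([0.0, 1.0]))
        assert ID[0, 1] == pytest.approx(1.0)

    def test_half_ratio_value(self):
        # ratio r = |1/3 - 1|/ (1/3 + 1)... use x = (1, 1/3): r = (2/3)/(4/3) = 0.5
        ID = information_difference(np.array([1.0, 1.0 / 3.0]))
        assert ID[0, 1] == pytest.approx(np.exp(-1.0), rel=1e-12)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            information_difference(np.array([0.5, 1.2]))

    @settings(max_examples=1000, deadline=None)
    @given(x=unit, y=unit)
    def test_bounded_and_symmetric(self, x, y):
        ID = information_difference(np.array([x, y]))
        assert 0.0 <= ID[0, 1] <= 1.0
        assert ID[0, 1] == ID[1, 0]

    def test_monotone_in_gap_at_fixed_sum(self):
        # pairs with equal sum but growing |difference| must have growing ID
        total = 1.0
        gaps = np.linspace(0.0, 1.0, 25)
        vals = []
        for g in gaps:
            x, y = (total + g) / 2, (total - g) / 2
            vals.append(information_difference(np.array([x, y]))[0, 1])
        assert np.all(np.diff(vals) >= 0)
        rng = np.random.default_rng(0)
        for _ in range(1000):
            s = rng.uniform(0.2, 2.0)
            g1, g2 = np.sort(rng.uniform(0, min(s, 2 - s), size=2))
            v1 = information_difference(np.array([(s + g1) / 2, (s - g1) / 2]))[0, 1]
            v2 = information_difference(np.array([(s + g2) / 2, (s - g2) / 2]))[0, 1]
            assert v1 <= v2 + 1e-12


class TestTriangularFuzzyNumber:
    def test_constant_vector_gives_zero_tfn(self):
        tfn = triangular_fuzzy_number(information_difference(np.full(5, 0.3)))
        assert (tfn.L, tfn.M, tfn.T) == (0.0, 0.0, 0.0)

    def test_uniform_id_closed_form(self):
        m, v = 6, 0.4
        ID = np.full((m, m), v)
        np.fill_diagonal(ID, 0.0)
        tfn = triangular_fuzzy_number(ID)
        expected = v * (m - 1) / m
        assert tfn.L == pytest.approx(expected)
        assert tfn.M == pytest.approx(expected)
        assert tfn.T == pytest.approx(expected)

    @settings(max_examples=200, deadline=None)
    @given(st.lists(unit, min_size=2, max_size=8))
    def test_ordering_invariant(self, values):
        tfn = triangular_fuzzy_number(information_difference(np.array(values)))
        assert 0.0 <= tfn.L <= tfn.M <= tfn.T <= 1.0

    def test_invalid_ordering_rejected(self):
        with pytest.raises(ValueError):
            TriangularFuzzyNumber(L=0.5, M=0.2, T=0.9)


class TestTFSimilarity:
    def test_equal_tfns_similarity_one(self):
        a = TriangularFuzzyNumber(0.2, 0.3, 0.5)
        assert tf_similarity(a, a) == pytest.approx(1.0)

    def test_extreme_pair_similarity_zero(self):
        lo = TriangularFuzzyNumber(0, 0, 0)
        hi = TriangularFuzzyNumber(1, 1, 1)
        assert tf_similarity(lo, hi) == pytest.approx(0.0)
        assert tf_similarity(hi, lo) == pytest.approx(0.0)

    def test_hand_value_half(self):
        a = TriangularFuzzyNumber(0, 0, 0)
        b = TriangularFuzzyNumber(0.5, 0.5, 0.5)
        assert tf_similarity(a, b) == pytest.approx(0.5)

    @settings(max_examples=1000, deadline=None)
    @given(a=st.tuples(unit, unit, unit), b=st.tuples(unit, unit, unit))
    def test_symmetric_and_bounded(self, a, b):
        ta = TriangularFuzzyNumber(*np.sort(a))
        tb = TriangularFuzzyNumber(*np.sort(b))
        s = tf_similarity(ta, tb)
        assert s == pytest.approx(tf_similarity(tb, ta))
        assert 0.0 <= s <= 1.0

    def test_similarity_matrix_matches_pairwise(self, rng):
        tfns = [TriangularFuzzyNumber(*np.sort(rng.uniform(size=3))) for _ in range(6)]
        S = similarity_matrix(tfns)
        for i in range(6):
            for j in range(6):
                assert S[i, j] == pytest.approx(tf_similarity(tfns[i], tfns[j]))


class TestDeltaLevelClasses:
    def test_strict_threshold(self):
        row = np.array([1.0, 0.2, 0.35, 0.9])
        similar, dissimilar = delta_level_classes(row, 0.3, i=0)
        assert set(similar) == {2, 3}
        assert set(dissimilar) == {1}

    def test_delta_one_empty(self):
        row = np.ones(4)
        similar, _ = delta_level_classes(row, 1.0, i=0)
        assert similar.size == 0

    def test_delta_monotone_shrinkage(self, rng):
        row = rng.uniform(size=20)
        sizes = [delta_level_classes(row, d, i=3)[0].size for d in np.linspace(0, 1, 11)]
        assert np.all(np.diff(sizes) <= 0)

    def test_invalid_delta_rejected(self):
        with pytest.raises(ValueError):
            delta_level_classes(np.ones(3), 1.5, i=0)


class TestMembershipProbability:
    def test_full_agreement(self):
        sim = np.ones((3, 3))
        labels = np.array([1, 1, 1])
        assert membership_probability(sim, labels, 0.5, 0) == 1.0

    def test_empty_neighbourhood_is_half(self):
        sim = np.zeros((3, 3))
        labels = np.array([1, 2, 1])
        assert membership_probability(sim, labels, 0.5, 0) == 0.5

    def test_three_of_four_agree(self):
        sim = np.ones((5, 5))
        labels = np.array([1, 1, 1, 1, 2])
        assert membership_probability(sim, labels, 0.5, 0) == pytest.approx(0.75)


class TestThresholds:
    def test_worked_cost_matrix(self):
        costs = CostMatrix(lPP=0, lBP=2, lNP=6, lNN=0, lBN=2, lPN=8)
        alpha, beta = thresholds_from_costs(costs)
        assert alpha == pytest.approx(0.75)
        assert beta == pytest.approx(1.0 / 3.0)

    def test_scale_invariance(self):
        a1 = thresholds_from_costs(CostMatrix(0, 2, 6, 0, 2, 8))
        a2 = thresholds_from_costs(CostMatrix(0, 20, 60, 0, 20, 80))
        assert a1 == pytest.approx(a2)

    def test_degenerate_costs_rejected(self):
        with pytest.raises(ValueError):
            thresholds_from_costs(CostMatrix(0, 1, 2, 0, 1, 2))


class TestPartitionRegions:
    def test_boundary_conventions(self):
        # closed at alpha (Pos), closed at beta (Neg), open boundary region
        p = np.array([0.75, 0.7499, 0.33, 0.3299])
        part = partition_regions(p, alpha=0.75, beta=0.33)
        assert 0 in part.pos and 1 in part.bnd
        assert 2 in part.neg and 3 in part.neg

    def test_enumerated_example(self):
        part = partition_regions(np.array([0.9, 0.5, 0.1]), alpha=0.75, beta=0.33)
        assert list(part.pos) == [0]
        assert list(part.bnd) == [1]
        assert list(part.neg) == [2]

    @settings(max_examples=300, deadline=None)
    @given(
        probs=st.lists(unit, min_size=1, max_size=30),
        thr=st.tuples(unit, unit).filter(lambda t: abs(t[0] - t[1]) > 1e-6),
    )
    def test_always_partitions(self, probs, thr):
        beta, alpha = sorted(thr)
        part = partition_regions(np.array(probs), alpha=alpha, beta=beta)
        assert part.n == len(probs)
        assert set(part.pos) | set(part.bnd) | set(part.neg) == set(range(len(probs)))

    def test_monotone_in_alpha_and_beta(self, rng):
        p = rng.uniform(size=100)
        pos_sizes = [partition_regions(p, a, 0.2).pos.size for a in (0.5, 0.7, 0.9)]
        assert np.all(np.diff(pos_sizes) <= 0)
        neg_sizes = [partition_regions(p, 0.95, b).neg.size for b in (0.2, 0.5, 0.8)]
        assert np.all(np.diff(neg_sizes) >= 0)

    def test_alpha_below_beta_rejected(self):
        with pytest.raises(ValueError):
            partition_regions(np.array([0.5]), alpha=0.3, beta=0.6)


class TestTriage:
    def test_minmax_scaling_and_partition_cover(self, rng):
        Zt = rng.standard_normal((4, 30))
        X01 = minmax_scale_attributes(Zt)
        assert X01.min() >= 0.0 and X01.max() <= 1.0
        labels = rng.integers(1, 3, size=30)
        part, probs = triage(Zt, labels, delta=0.3, alpha=0.75, beta=0.55)
        assert part.n == 30
        assert probs.shape == (30,)
        assert np.all((probs >= 0) & (probs <= 1))

    def test_constant_attribute_maps_to_zero(self):
        Z = np.vstack([np.ones(5), np.arange(5.0)])
        X01 = minmax_scale_attributes(Z)
        np.testing.assert_allclose(X01[0], 0.0)
        np.testing.assert_allclose(X01[1], np.linspace(0, 1, 5))
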