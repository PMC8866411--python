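import itertools
import math
import statistics

import numpy as np
import pytest
from hypothesis import given, strategies as st

from newtblur.blurring import (
    basic_average,
    edge_survival_count,
    enumerate_subsets,
    newtonian_blur,
    surviving_edges,
    trimmed_mean,
)
from newtblur.graph_model import AugmentationConfig, Parcellation, ValidationError

from conftest import ensemble_from_matrix, random_ensemble


def oracle_trimmed_mean(weights, trim):
    """Independent oracle: remove one min- and one max-occurrence per step."""
    vals = list(weights)
    for _ in range(trim):
        vals.remove(max(vals))
        vals.remove(min(vals))
    return statistics.mean(vals)


class TestEnumerateSubsets:
    def test_ten_choose_seven_gives_120(self):
        subsets = enumerate_subsets(10, 7)
        assert len(subsets) == 120

    def test_small_exhaustive_case(self):
        assert enumerate_subsets(3, 2) == [(0, 1), (0, 2), (1, 2)]

    def test_k_equals_R_single_subset(self):
        assert enumerate_subsets(5, 5) == [(0, 1, 2, 3, 4)]

    @pytest.mark.parametrize("R,k", [(3, 4), (3, 0)])
    def test_invalid_sizes_rejected(self, R, k):
        with pytest.raises(ValidationError):
            enumerate_subsets(R, k)

    @given(R=st.integers(1, 8), k=st.integers(1, 8))
    def test_count_and_lexicographic_order(self, R, k):
        if k > R:
            return
        subsets = enumerate_subsets(R, k)
        assert len(subsets) == math.comb(R, k)
        assert subsets == sorted(set(subsets))
        assert all(s == tuple(sorted(s)) for s in subsets)


class TestTrimmedMean:
    @pytest.mark.parametrize(
        "weights,trim,expected",
        [
            ([1, 2, 3, 4, 5, 6, 7], 1, 4.0),
            ([5, 5, 5, 5, 5, 5, 5], 1, 5.0),  # ties: one occurrence per extreme
            ([2, 2, 9, 9, 9, 1, 10], 1, 6.2),
        ],
    )
    def test_worked_examples(self, weights, trim, expected):
        assert trimmed_mean(weights, trim) == pytest.approx(expected)

    def test_matches_removal_oracle_on_random_lists(self):
        rng = np.random.default_rng(42)
        for _ in range(1000):
            k = int(rng.integers(3, 12))
            trim = int(rng.integers(0, (k - 1) // 2 + 1))
            # small integer weights force frequent ties; occasionally all-equal
            if rng.random() < 0.05:
                weights = [float(rng.integers(1, 5))] * k
            else:
                weights = rng.integers(1, 6, size=k).astype(float).tolist()
            assert trimmed_mean(weights, trim) == pytest.approx(
                oracle_trimmed_mean(weights, trim)
            )

    def test_too_few_weights_rejected(self):
        with pytest.raises(ValidationError):
            trimmed_mean([1.0, 2.0], 1)

    @given(
        st.lists(st.floats(0.5, 1e6), min_size=3, max_size=11),
        st.integers(0, 4),
    )
    def test_bounded_by_input_extremes(self, weights, trim):
        if len(weights) - 2 * trim < 1:
            return
        value = trimmed_mean(weights, trim)
        assert min(weights) - 1e-9 <= value <= max(weights) + 1e-9

    @given(
        st.lists(st.integers(1, 50), min_size=3, max_size=9),
        st.integers(0, 3),
        st.data(),
    )
    def test_monotone_in_any_single_weight(self, weights, trim, data):
        if len(weights) - 2 * trim < 1:
            return
        i = data.draw(st.integers(0, len(weights) - 1))
        bump = data.draw(st.integers(1, 20))
        before = trimmed_mean(weights, trim)
        bumped = list(weights)
        bumped[i] += bump
        assert trimmed_mean(bumped, trim) >= before - 1e-12


class TestSurvivingEdges:
    def test_zero_filter_applies_within_subset_only(self, parc5):
        # (1,2) is zero only in run 2, which the subset omits: it survives
        edges = [(1, 2), (1, 3)]
        W = [[5, 1], [4, 0], [0, 2]]
        ens = ensemble_from_matrix(parc5, edges, W)
        assert surviving_edges(ens, (0, 1)) == {(1, 2)}
        assert surviving_edges(ens, (0, 2)) == {(1, 3)}
        assert surviving_edges(ens, (0, 1, 2)) == set()

    def test_empty_runs_yield_empty_set(self, parc5):
        ens = ensemble_from_matrix(parc5, [], [[], [], []])
        assert surviving_edges(ens, (0, 1, 2)) == set()

    def test_invalid_run_index_rejected(self, parc5):
        ens = ensemble_from_matrix(parc5, [(1, 2)], [[1.0], [2.0]])
        with pytest.raises(ValidationError, match="out of range"):
            surviving_edges(ens, (0, 5))


class TestNewtonianBlur:
    def test_identical_runs_reproduce_the_input_graph(self, parc5):
        edges = [(1, 2), (2, 3), (4, 5)]
        W = [[7, 3, 11]] * 10
        ens = ensemble_from_matrix(parc5, edges, W)
        augmented = newtonian_blur(ens, AugmentationConfig())
        assert len(augmented) == 120
        for _, g in augmented.items:
            assert g.edges == {(1, 2): 7.0, (2, 3): 3.0, (4, 5): 11.0}

    def test_edge_zero_in_one_run_survives_in_36_of_120(self, parc5):
        W = [[float(r + 1)] for r in range(10)]
        W[3][0] = 0.0  # absent in run 3 only
        ens = ensemble_from_matrix(parc5, [(1, 2)], W)
        augmented = newtonian_blur(ens, AugmentationConfig())
        present = sum((1, 2) in g.edges for g in augmented.graphs)
        assert present == 36
        assert len(augmented) - present == 84
        # present exactly in the subsets that avoid run 3
        for subset, g in augmented.items:
            assert ((1, 2) in g.edges) == (3 not in subset)

    def test_weights_match_scalar_trimmed_mean(self, parc10):
        rng = np.random.default_rng(3)
        ens, edges, W = random_ensemble(rng, parc10, n_edges=12, R=6)
        cfg = AugmentationConfig(R=6, k=4, trim=1)
        augmented = newtonian_blur(ens, cfg)
        assert len(augmented) == math.comb(6, 4)
        for subset, g in augmented.items:
            for j, e in enumerate(edges):
                weights = [W[i][j] for i in subset]
                if all(w > 0 for w in weights):
                    assert g.weight(*e) == pytest.approx(
                        trimmed_mean(weights, 1), abs=1e-12
                    )
                else:
                    assert e not in g.edges

    @pytest.mark.parametrize("R,k,trim", [(4, 2, 0), (5, 3, 1), (8, 5, 2), (6, 6, 1)])
    def test_item_count_is_R_choose_k(self, parc10, R, k, trim):
        rng = np.random.default_rng(R * 100 + k)
        ens, _, _ = random_ensemble(rng, parc10, n_edges=8, R=R)
        augmented = newtonian_blur(ens, AugmentationConfig(R=R, k=k, trim=trim))
        assert len(augmented) == math.comb(R, k)
        assert [s for s, _ in augmented.items] == enumerate_subsets(R, k)

    def test_augmented_weights_bounded_by_subset_extremes(self, parc10):
        rng = np.random.default_rng(11)
        ens, edges, W = random_ensemble(rng, parc10, n_edges=10, R=7)
        augmented = newtonian_blur(ens, AugmentationConfig(R=7, k=5, trim=1))
        for subset, g in augmented.items:
            for j, e in enumerate(edges):
                if e in g.edges:
                    weights = [W[i][j] for i in subset]
                    assert min(weights) <= g.edges[e] <= max(weights)


class TestBasicAverage:
    def test_extremes_dropped_before_averaging(self, parc5):
        W = [[10.0]] * 8 + [[1.0], [100.0]]
        ens = ensemble_from_matrix(parc5, [(1, 2)], W)
        assert basic_average(ens).edges == {(1, 2): 10.0}

    def test_edge_absent_in_any_run_is_dropped(self, parc5):
        W = [[5.0, 2.0]] * 9 + [[5.0, 0.0]]
        ens = ensemble_from_matrix(parc5, [(1, 2), (3, 4)], W)
        assert basic_average(ens).edges == {(1, 2): 5.0}

    def test_identical_runs_are_a_fixed_point(self, parc5):
        edges = [(1, 2), (2, 5)]
        W = [[4, 9]] * 10
        ens = ensemble_from_matrix(parc5, edges, W)
        assert basic_average(ens) == ens.runs[0]

    def test_equals_single_graph_of_full_subset_augmentation(self, parc10):
        rng = np.random.default_rng(5)
        for R in (3, 5, 10):
            ens, _, _ = random_ensemble(rng, parc10, n_edges=15, R=R)
            augmented = newtonian_blur(ens, AugmentationConfig(R=R, k=R, trim=1))
            assert len(augmented) == 1
            assert basic_average(ens) == augmented.items[0][1]

    def test_fewer_than_three_runs_rejected(self, parc5):
        ens = ensemble_from_matrix(parc5, [(1, 2)], [[1.0], [2.0]])
        with pytest.raises(ValidationError):
            basic_average(ens)


class TestEdgeSurvivalCount:
    @pytest.mark.parametrize(
        "zero_runs,expected", [(0, 120), (1, 36), (2, 8), (3, 1), (4, 0), (10, 0)]
    )
    def test_closed_form_at_default_config(self, zero_runs, expected):
        assert edge_survival_count(zero_runs, AugmentationConfig()) == expected

    def test_out_of_range_zero_runs_rejected(self):
        with pytest.raises(ValidationError):
            edge_survival_count(11, AugmentationConfig())

    @given(R=st.integers(2, 8), k=st.integers(1, 8), z=st.integers(0, 8))
    def test_matches_brute_force_subset_enumeration(self, R, k, z):
        if k > R or z > R or k - 2 * 0 < 1:
            return
        cfg = AugmentationConfig(R=R, k=k, trim=0)
        zero_set = set(range(z))  # which runs are zero is immaterial by symmetry
        brute = sum(
            1
            for subset in itertools.combinations(range(R), k)
            if zero_set.isdisjoint(subset)
        )
        assert edge_survival_count(z, cfg) == brute

    def test_pascal_identity_partitions_the_subsets(self):
        cfg = AugmentationConfig()
        containing_zero_run = math.comb(cfg.R - 1, cfg.k - 1)
        assert edge_survival_count(1, cfg) + containing_zero_run == cfg.n_subsets
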