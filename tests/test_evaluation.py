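from itertools import combinations

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from dekernet import (
    DirectedWeightMatrix,
    GoldStandard,
    InferredNetwork,
    classify_edges,
    net_positive_score,
    pr_curves,
    threshold_sweep,
)
from oracles import brute_force_classify


def gold_of(pairs, names):
    return GoldStandard(
        true_edges=frozenset(tuple(sorted(p)) for p in pairs), feature_names=names
    )


class TestClassifyEdges:
    def test_triplet_indirect_error(self, triplet_gold):
        cls = classify_edges({("a", "b"), ("a", "c")}, triplet_gold)
        assert cls.true_positives == (("a", "b"),)
        assert cls.indirect_false_positives == (("a", "c"),)  # via b
        assert cls.other_false_positives == ()
        assert cls.false_negatives == (("b", "c"),)

    def test_isolated_endpoint_is_other_error(self, triplet_gold):
        cls = classify_edges({("a", "d")}, triplet_gold)
        assert cls.other_false_positives == (("a", "d"),)

    def test_perfect_inference(self, triplet_gold):
        cls = classify_edges(set(triplet_gold.true_edges), triplet_gold)
        assert cls.n_tp == 2
        assert cls.n_fp == 0
        assert cls.false_negatives == ()

    def test_unknown_feature_rejected(self, triplet_gold):
        with pytest.raises(ValueError):
            classify_edges({("a", "zzz")}, triplet_gold)

    def test_exhaustive_agreement_with_brute_force_on_small_graphs(self):
        # all gold graphs on 5 nodes x random inferred sets, plus random
        # 7-node pairs: matches the common-neighbor enumeration oracle
        rng = np.random.default_rng(0)
        nodes5 = tuple("abcde")
        pairs5 = list(combinations(nodes5, 2))
        for trial in range(60):
            gold_pairs = {p for p in pairs5 if rng.random() < 0.3}
            inferred = {p for p in pairs5 if rng.random() < 0.3}
            gold = gold_of(gold_pairs, nodes5)
            cls = classify_edges(inferred, gold)
            tp, ifp, ofp, fn = brute_force_classify(inferred, gold_pairs, nodes5)
            assert set(cls.true_positives) == tp
            assert set(cls.indirect_false_positives) == ifp
            assert set(cls.other_false_positives) == ofp
            assert set(cls.false_negatives) == fn

    @settings(deadline=None, max_examples=40, derandomize=True)
    @given(st.integers(0, 2**20), st.integers(0, 2**20))
    def test_conservation_identities(self, seed_gold, seed_inf):
        nodes = tuple("abcdefg")
        pairs = list(combinations(nodes, 2))
        r1 = np.random.default_rng(seed_gold)
        r2 = np.random.default_rng(seed_inf)
        gold_pairs = {p for p in pairs if r1.random() < 0.35}
        inferred = {p for p in pairs if r2.random() < 0.35}
        cls = classify_edges(inferred, gold_of(gold_pairs, nodes))
        assert cls.n_tp + cls.n_fp == len(inferred)
        assert cls.n_tp + len(cls.false_negatives) == len(gold_pairs)


class TestPrCurves:
    def test_hand_counted_full_network_point(self, triplet_gold):
        ranking = [("a", "b", 0.9), ("a", "c", 0.5), ("b", "d", 0.1)]
        curve = pr_curves(ranking, triplet_gold)
        kept, recall, prec_incl, prec_excl = curve.points[0]
        assert kept == 3
        assert recall == pytest.approx(0.5)
        assert prec_incl == pytest.approx(1 / 3)  # a-c indirect, b-d other
        assert prec_excl == pytest.approx(1 / 2)

    def test_perfect_ranking_has_unit_precision_everywhere(self, triplet_gold):
        ranking = [("a", "b", 0.9), ("b", "c", 0.8)]
        curve = pr_curves(ranking, triplet_gold)
        for kept, recall, p_incl, p_excl in curve.points:
            assert p_incl == 1.0 and p_excl == 1.0
        assert curve.points[0][1] == 1.0  # full ranking recalls everything

    def test_invariants_on_random_rankings(self):
        rng = np.random.default_rng(3)
        nodes = tuple("abcdef")
        pairs = list(combinations(nodes, 2))
        for _ in range(25):
            gold_pairs = {p for p in pairs if rng.random() < 0.4} or {pairs[0]}
            ranked = [
                (a, b, float(rng.random())) for a, b in pairs if rng.random() < 0.6
            ]
            if not ranked:
                continue
            curve = pr_curves(ranked, gold_of(gold_pairs, nodes))
            recalls = [pt[1] for pt in curve.points]
            # points are ordered by descending kept count: recall non-increasing
            assert all(r1 >= r2 for r1, r2 in zip(recalls, recalls[1:]))
            for _, _, p_incl, p_excl in curve.points:
                assert p_excl >= p_incl - 1e-12

    def test_tie_break_is_canonical_pair_order(self, triplet_gold):
        ranking = [("b", "d", 0.5), ("a", "b", 0.5)]
        curve = pr_curves(ranking, triplet_gold)
        # one kept edge: must be (a, b) by canonical order, a true positive
        last = curve.points[-1]
        assert last[0] == 1 and last[2] == 1.0

    def test_empty_gold_rejected(self):
        gold = GoldStandard(true_edges=frozenset(), feature_names=("a", "b"))
        with pytest.raises(ValueError):
            pr_curves([("a", "b", 1.0)], gold)


class TestNetPositiveScore:
    def test_subtraction(self, triplet_gold):
        inferred = {("a", "b"), ("b", "c"), ("a", "c"), ("a", "d"), ("b", "d")}
        # TP = 2, FP = 3
        assert net_positive_score(inferred, triplet_gold) == -1

    def test_empty_network_scores_zero(self, triplet_gold):
        assert net_positive_score(set(), triplet_gold) == 0

    def test_complement_of_gold_is_minus_size(self):
        nodes = tuple("abcd")
        gold_pairs = {("a", "b"), ("c", "d")}
        complement = set(combinations(nodes, 2)) - gold_pairs
        score = net_positive_score(complement, gold_of(gold_pairs, nodes))
        assert score == -len(complement)

    def test_score_equals_size_iff_subset_of_gold(self):
        nodes = tuple("abcd")
        gold_pairs = {("a", "b"), ("b", "c"), ("c", "d")}
        gold = gold_of(gold_pairs, nodes)
        for r in range(3):
            for subset in combinations(sorted(gold_pairs), r + 1):
                assert net_positive_score(set(subset), gold) == len(subset)
        for inferred in [{("a", "c")}, {("a", "b"), ("a", "d")}]:
            assert net_positive_score(inferred, gold) < len(inferred)


class TestThresholdSweep:
    def make_W(self, rng, n=10):
        M = rng.uniform(size=(n, n))
        np.fill_diagonal(M, 0.0)
        names = tuple(f"G{i}" for i in range(n))
        return DirectedWeightMatrix(W=M, feature_names=names), names

    def test_full_fraction_keeps_every_pair(self, rng):
        W, names = self.make_W(rng)
        gold = gold_of({("G0", "G1"), ("G2", "G3")}, names)
        (cls, net), = threshold_sweep(W, gold, fractions=(1.0,)).values()
        assert cls.n_inferred == 45
        assert cls.recall() == 1.0

    def test_tiny_fraction_keeps_single_max_weight_pair(self, rng):
        W, names = self.make_W(rng)
        gold = gold_of({("G0", "G1")}, names)
        from dekernet import collapse_to_undirected

        collapsed = collapse_to_undirected(W)
        best = max(collapsed, key=collapsed.get)
        (cls, _), = threshold_sweep(W, gold, fractions=(0.001,)).values()
        assert cls.n_inferred == 1
        inferred = set(cls.true_positives + cls.indirect_false_positives + cls.other_false_positives)
        assert inferred == {best}

    def test_fraction_count_uses_floor(self, rng):
        W, names = self.make_W(rng, n=10)  # 45 pairs
        gold = gold_of({("G0", "G1")}, names)
        (cls, _), = threshold_sweep(W, gold, fractions=(0.1,)).values()
        assert cls.n_inferred == 4  # floor(4.5)

    def test_bad_fraction_rejected(self, rng):
        W, names = self.make_W(rng)
        gold = gold_of({("G0", "G1")}, names)
        with pytest.raises(ValueError):
            threshold_sweep(W, gold, fractions=(0.0,))
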