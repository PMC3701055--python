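import itertools

import numpy as np
import pytest

import oracles
from grninfer import (
    GoldStandard,
    RankedEdgeList,
    borda_integrate,
    evaluate_auc,
    evaluate_directionality,
)


def make_list(pairs_scores, directed=True, tag="m"):
    return RankedEdgeList(pairs_scores, directed=directed, method_tag=tag)


class TestBorda:
    def test_requires_two_lists(self):
        with pytest.raises(ValueError, match=">= 2"):
            borda_integrate([make_list([("a", "b", 1.0)])])

    def test_consensus_fixed_point(self):
        edges = [("a", "b", 0.9), ("a", "c", 0.7), ("b", "c", 0.4)]
        l1 = make_list(edges, tag="m1")
        l2 = make_list(edges, tag="m2")
        composite = borda_integrate([l1, l2])
        assert list(zip(composite.regulators, composite.targets)) == [
            ("a", "b"), ("a", "c"), ("b", "c"),
        ]

    def test_tie_broken_lexicographically(self):
        # A ranks (e1, e2) = (1, 2); B ranks (2, 1) -> both average 1.5
        a = make_list([("x", "y", 0.9), ("u", "v", 0.1)], tag="a")
        b = make_list([("u", "v", 0.9), ("x", "y", 0.1)], tag="b")
        composite = borda_integrate([a, b])
        assert composite.meta[0]["average_rank"] == 1.5
        assert composite.meta[1]["average_rank"] == 1.5
        assert (composite.regulators[0], composite.targets[0]) == ("u", "v")

    def test_absence_penalty_rank(self):
        shared = [(f"g{i}", f"h{i}", 1.0 - i / 100) for i in range(1, 6)]
        only_a = [("aa", "bb", 0.999)]
        a = make_list(only_a + shared, tag="a")
        b = make_list(shared, tag="b")
        c = make_list(shared, tag="c")
        composite = borda_integrate([a, b, c], top_k=100)
        k = list(zip(composite.regulators, composite.targets)).index(("aa", "bb"))
        assert composite.meta[k]["average_rank"] == pytest.approx((1 + 101 + 101) / 3)
        assert composite.meta[k]["supporting_methods"] == {"a"}

    def test_input_order_symmetric(self):
        rng = np.random.default_rng(0)
        lists = [
            make_list([(f"g{i}", f"h{i}", s) for i, s in enumerate(rng.random(20))], tag=f"m{k}")
            for k in range(3)
        ]
        outs = [borda_integrate(list(p), top_k=10) for p in itertools.permutations(lists)]
        first = outs[0]
        for other in outs[1:]:
            assert other == first

    def test_direction_votes_mix_directed_and_undirected(self):
        directed = make_list([("a", "b", 0.9)], directed=True, tag="d")
        undirected = make_list([("a", "b", 0.8)], directed=False, tag="u")
        composite = borda_integrate([directed, undirected])
        assert not composite.directed
        assert composite.meta[0]["orientation"] == "forward"
        # opposite orientations cancel to undirected
        reverse = make_list([("b", "a", 0.7)], directed=True, tag="r")
        composite2 = borda_integrate([directed, reverse, undirected])
        assert composite2.meta[0]["orientation"] is None


class TestEvaluateAUC:
    def gold(self):
        labels = {(f"p{i}", f"q{i}"): 1 for i in range(5)}
        labels.update({(f"n{i}", f"m{i}"): 0 for i in range(5)})
        return GoldStandard(labels, directed=True)

    def test_perfect_and_reversed(self):
        gold = self.gold()
        pairs = list(gold.positives) + list(gold.negatives)
        perfect = make_list([(a, b, 1.0 - 0.01 * k) for k, (a, b) in enumerate(pairs)])
        assert evaluate_auc(perfect, gold).auroc == pytest.approx(1.0)
        reverse = make_list([(a, b, 0.01 * k) for k, (a, b) in enumerate(pairs)])
        assert evaluate_auc(reverse, gold).auroc == pytest.approx(0.0)

    def test_random_ordering_near_half(self):
        gold = self.gold()
        pairs = list(gold.positives) + list(gold.negatives)
        rocs = []
        for seed in range(200):
            rng = np.random.default_rng(seed)
            scores = rng.permutation(len(pairs)) / len(pairs)
            rocs.append(evaluate_auc(make_list(list(zip(*zip(*pairs), scores))), gold).auroc)
        assert np.mean(rocs) == pytest.approx(0.5, abs=0.03)

    def test_matches_exhaustive_oracle_full_coverage(self, rng):
        # random scored universes of <= 20 gold pairs, fully covered
        for seed in range(25):
            r = np.random.default_rng(seed)
            n_pairs = int(r.integers(4, 21))
            labels = {(f"a{i}", f"b{i}"): int(r.random() < 0.4) for i in range(n_pairs)}
            if not (0 < sum(labels.values()) < n_pairs):
                continue
            gold = GoldStandard(labels, directed=True)
            scores = np.round(r.random(n_pairs), 2)  # coarse grid forces ties
            pred = make_list([(a, b, s) for (a, b), s in zip(labels, scores)])
            res = evaluate_auc(pred, gold)
            want_roc, want_pr = oracles.exhaustive_auc(
                [(s, labels[p]) for p, s in zip(labels, scores)]
            )
            assert res.auroc == pytest.approx(want_roc, abs=1e-12)
            assert res.aupr == pytest.approx(want_pr, abs=1e-12)

    def test_agrees_with_sklearn_on_full_coverage(self, rng):
        from sklearn.metrics import roc_auc_score

        labels = {(f"a{i}", f"b{i}"): int(i < 8) for i in range(30)}
        gold = GoldStandard(labels, directed=True)
        scores = rng.random(30)
        pred = make_list([(a, b, s) for (a, b), s in zip(labels, scores)])
        ours = evaluate_auc(pred, gold).auroc
        assert ours == pytest.approx(roc_auc_score([labels[p] for p in labels], scores), abs=1e-12)

    def test_truncation_tail_is_expected_random_completion(self):
        # 2 positives ranked, 2 positives + 4 negatives beyond the cut:
        # ROC continues as the diagonal of the remaining block
        labels = {(f"p{i}", f"q{i}"): 1 for i in range(4)}
        labels.update({(f"n{i}", f"m{i}"): 0 for i in range(4)})
        gold = GoldStandard(labels, directed=True)
        pred = make_list([("p0", "q0", 0.9), ("p1", "q1", 0.8)])
        res = evaluate_auc(pred, gold, top_k=2)
        # ranked part: TPR reaches 0.5 at FPR 0; tail: straight line to (1,1)
        # area = 0.5*(0.5+1)/1 ... trapezoid of [(0,0.5),(1,1)] + 0
        assert res.auroc == pytest.approx(0.75)

    def test_unlabeled_pairs_ignored(self):
        gold = GoldStandard({("a", "b"): 1, ("c", "d"): 0}, directed=True)
        pred = make_list([("zz", "yy", 0.99), ("a", "b", 0.5), ("c", "d", 0.1)])
        assert evaluate_auc(pred, gold).auroc == pytest.approx(1.0)

    def test_degenerate_gold_rejected(self):
        with pytest.raises(ValueError):
            evaluate_auc(make_list([("a", "b", 1.0)]), GoldStandard({("a", "b"): 1}))


class TestDirectionality:
    def test_perfect_prediction(self):
        gold = GoldStandard({("a", "b"): 1, ("b", "c"): 1}, directed=True)
        pred = RankedEdgeList(
            [("a", "b", 1.0), ("b", "c", 0.9)],
            directed=False,
            meta=[{"orientation": "forward"}, {"orientation": "forward"}],
        )
        d = evaluate_directionality(pred, gold)
        assert d.directed_precision == 1.0 and d.n_tp == 2

    def test_all_undirected_is_degenerate(self):
        gold = GoldStandard({("a", "b"): 1}, directed=True)
        pred = RankedEdgeList([("a", "b", 1.0)], directed=False, meta=[{"orientation": None}])
        d = evaluate_directionality(pred, gold)
        assert d.degenerate and d.directed_precision == 0.0 and d.n_directed == 0

    def test_hand_enumerated_counts(self):
        # 4 predicted edges (3 directed), 2 skeleton TPs, 1 correctly directed
        gold = GoldStandard({("a", "b"): 1, ("c", "d"): 1, ("x", "y"): 1}, directed=True)
        pred = RankedEdgeList(
            [("a", "b", 0.9), ("c", "d", 0.8), ("e", "f", 0.7), ("g", "h", 0.6)],
            directed=False,
            meta=[
                {"orientation": "forward"},   # a->b correct
                {"orientation": "backward"},  # d->c wrong direction
                {"orientation": "forward"},   # not in gold
                {"orientation": None},        # undirected, not in gold
            ],
        )
        d = evaluate_directionality(pred, gold)
        assert (d.n_edges, d.n_directed, d.n_tp, d.n_tp_correct_direction) == (4, 3, 2, 1)
        assert d.directed_precision == pytest.approx(1 / 3)

    def test_undirected_gold_rejected(self):
        gold = GoldStandard({("a", "b"): 1, ("a", "c"): 0}, directed=False)
        pred = RankedEdgeList([("a", "b", 1.0)], directed=False, meta=[{"orientation": "forward"}])
        with pytest.raises(ValueError):
            evaluate_directionality(pred, gold)
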