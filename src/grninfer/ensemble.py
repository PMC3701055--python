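"""Borda-count integration of ranked edge lists and DREAM-style evaluation.

Integration rescores each edge by its average rank across the constituent
methods' (truncated) rankings — the Borda count.  Evaluation compares a
ranked edge list against a binary gold standard restricted to the labeled
pairs, sweeping pruning thresholds down the list to build ROC and
precision-recall curves; gold pairs missing from the (truncated) prediction
complete the curves under the convention that the remainder is randomly
ordered.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from ._utils import logger
from .datatypes import GoldStandard, RankedEdgeList
from .plpc import PDAG

__all__ = [
    "ConfusionCounts",
    "EvalResult",
    "DirectionalityCounts",
    "borda_integrate",
    "evaluate_auc",
    "evaluate_directionality",
]


@dataclass
class ConfusionCounts:
    n_tp: int
    n_fp: int
    n_tn: int
    n_fn: int

    @property
    def recall(self) -> float:
        d = self.n_tp + self.n_fn
        return self.n_tp / d if d else 0.0

    @property
    def precision(self) -> float:
        d = self.n_tp + self.n_fp
        return self.n_tp / d if d else 0.0

    @property
    def fpr(self) -> float:
        d = self.n_tn + self.n_fp
        return self.n_fp / d if d else 0.0


@dataclass
class EvalResult:
    aupr: float
    auroc: float
    roc_points: np.ndarray  # (k, 2) columns fpr, tpr
    pr_points: np.ndarray  # (k, 2) columns recall, precision
    top_k: int | None
    confusion: list[ConfusionCounts] = field(default_factory=list)


@dataclass
class DirectionalityCounts:
    """Table-style directionality summary for a partially directed network.

    n_tp counts skeleton matches against gold positives ignoring direction;
    n_tp_correct_direction counts directed predicted edges whose direction
    agrees with the gold edge.  directed_precision is
    n_tp_correct_direction / n_directed (0 with ``degenerate`` set when no
    edge was oriented).
    """

    n_edges: int
    n_directed: int
    n_tp: int
    n_tp_correct_direction: int
    directed_precision: float
    n_tp_directed: int = 0
    degenerate: bool = False


# ---------------------------------------------------------------------------
# Borda integration


def _pair_ranks_and_votes(elist: RankedEdgeList, top_k, use_directed_keys: bool):
    """Rank of every edge in one truncated list, plus direction votes.

    With undirected keys, a directed edge contributes the rank of its
    best-ranked orientation and votes for that orientation; an undirected
    edge with a PLPC-style orientation mark in its metadata votes too.
    """
    truncated = elist.top(top_k)
    ranks: dict[tuple, int] = {}
    votes: dict[tuple, set] = {}
    for pos, (a, b) in enumerate(zip(truncated.regulators, truncated.targets), start=1):
        if use_directed_keys:
            ranks.setdefault((a, b), pos)
            continue
        key = (a, b) if a <= b else (b, a)
        if key not in ranks:
            ranks[key] = pos
        if truncated.directed:
            votes.setdefault(key, set()).add((a, b))
        else:
            mark = truncated.meta[pos - 1].get("orientation")
            if mark == "forward":
                votes.setdefault(key, set()).add((a, b))
            elif mark == "backward":
                votes.setdefault(key, set()).add((b, a))
    return truncated, ranks, votes


def borda_integrate(lists: list[RankedEdgeList], top_k: int | None = None) -> RankedEdgeList:
    """Integrate K >= 2 ranked edge lists by Borda count.

    Each list is truncated to its ``top_k`` best edges; every edge appearing
    in at least one truncated list is rescored by its average rank across
    all K lists, edges absent from a list taking the penalty rank
    top_k + 1 (with top_k = the longest truncated list when unbounded).
    The integrative score is the negated average rank, so the usual
    larger-is-stronger convention holds and the composite ordering is by
    ascending average rank, ties broken lexicographically.

    Directed and undirected inputs mix: when any input is undirected the
    composite is keyed by unordered pair, and a composite edge is directed
    iff at least one method oriented it and none oriented it oppositely.
    Per-edge metadata records average rank, per-method ranks, supporting
    methods and the resolved direction.
    """
    if len(lists) < 2:
        raise ValueError(f"Borda integration needs >= 2 lists, got {len(lists)}")
    tags = []
    for i, l in enumerate(lists):
        tags.append(l.method_tag or f"method{i}")
    if len(set(tags)) != len(tags):
        tags = [f"{t}#{i}" for i, t in enumerate(tags)]
    use_directed_keys = all(l.directed for l in lists)

    per_method = [_pair_ranks_and_votes(l, top_k, use_directed_keys) for l in lists]
    if top_k is not None and not math.isinf(top_k):
        penalty = int(top_k) + 1
    else:
        penalty = max(len(t) for t, _, _ in per_method) + 1

    universe: set[tuple] = set()
    for _, ranks, _ in per_method:
        universe |= set(ranks)

    edges, meta = [], []
    for key in universe:
        ranks = {tag: r.get(key) for tag, (_, r, _) in zip(tags, per_method)}
        avg = sum(penalty if v is None else v for v in ranks.values()) / len(lists)
        supporting = {tag for tag, v in ranks.items() if v is not None}
        votes: set = set()
        for _, _, v in per_method:
            votes |= v.get(key, set())
        direction = votes.pop() if len(votes) == 1 else None
        if len(votes) > 1:
            logger.info("borda: conflicting directions for %s; left undirected", key)
        m = {
            "average_rank": avg,
            "ranks": ranks,
            "supporting_methods": frozenset(supporting),
        }
        if not use_directed_keys:
            m["orientation"] = None
            if direction is not None:
                m["orientation"] = "forward" if direction == key else "backward"
        edges.append((key[0], key[1], -avg))
        meta.append(m)
    return RankedEdgeList(edges, directed=use_directed_keys, method_tag="borda", meta=meta)


# ---------------------------------------------------------------------------
# AUC evaluation


def _gold_key_for(a: str, b: str, gold: GoldStandard, pred_directed: bool):
    """Gold keys matched by a predicted edge a->b (or pair {a,b})."""
    if gold.directed:
        if pred_directed:
            return [(a, b)] if (a, b) in gold.labels else []
        return [k for k in ((a, b), (b, a)) if k in gold.labels]
    key = (a, b) if a <= b else (b, a)
    return [key] if key in gold.labels else []


def evaluate_auc(
    pred: RankedEdgeList, gold: GoldStandard, top_k: int | None = 100_000
) -> EvalResult:
    """AUROC and AUPR of a ranked prediction against a binary gold standard.

    The evaluable universe is the set of pairs labeled in the gold standard;
    unlabeled pairs are ignored, not counted as negatives.  The prediction
    is truncated to its ``top_k`` highest-confidence edges, the curves are
    swept over pruning thresholds (edges with tied scores enter together),
    and gold pairs absent from the truncated list complete the curves under
    a random-ordering assumption for the remainder: a straight segment to
    (1, 1) on the ROC (its exact expectation) and the closed-form expected
    precision profile on the PR curve.  Both areas are trapezoidal.
    """
    n_pos = len(gold.positives)
    n_neg = len(gold.negatives)
    if n_pos == 0 or n_neg == 0:
        raise ValueError("gold standard must contain at least one positive and one negative")

    truncated = pred.top(top_k)
    # gold pairs in prediction order; first (best-ranked) match wins
    seen: set = set()
    ordered: list[tuple[float, int]] = []  # (score, label)
    for (a, b, s) in truncated:
        for key in _gold_key_for(a, b, gold, truncated.directed):
            if key not in seen:
                seen.add(key)
                ordered.append((float(s), gold.labels[key]))
    if not ordered:
        raise ValueError("no overlap between prediction and gold-standard universe")

    # sweep thresholds; tied scores enter together
    roc = [(0.0, 0.0)]
    pr: list[tuple[float, float]] = []
    confusion: list[ConfusionCounts] = []
    tp = fp = 0
    i = 0
    while i < len(ordered):
        j = i
        while j < len(ordered) and ordered[j][0] == ordered[i][0]:
            tp += ordered[j][1]
            fp += 1 - ordered[j][1]
            j += 1
        i = j
        cc = ConfusionCounts(tp, fp, n_neg - fp, n_pos - tp)
        confusion.append(cc)
        roc.append((cc.fpr, cc.recall))
        pr.append((cc.recall, cc.precision))

    # random-ordering completion for gold pairs beyond the truncated list
    pos_rest = n_pos - tp
    neg_rest = n_neg - fp
    if pos_rest + neg_rest > 0:
        roc.append((1.0, 1.0))  # straight segment = exact expectation of a random tail
    roc_arr = np.array(roc)
    auroc = float(np.trapezoid(roc_arr[:, 1], roc_arr[:, 0]))

    # PR: anchor recall=0 at the first achieved precision
    pr_arr = np.array([(0.0, pr[0][1])] + pr)
    aupr = float(np.trapezoid(pr_arr[:, 1], pr_arr[:, 0]))
    if pos_rest > 0:
        # expected precision while consuming the random tail:
        # after fraction t, TP = tp + t*pos_rest, found = ranked + t*(pos+neg rest)
        a0 = tp + fp
        m = pos_rest + neg_rest
        b = pos_rest
        # integral of (tp + t b)/(a0 + t m) dt over [0,1], times d(recall)/dt = b/n_pos
        if a0 == 0:
            integral = b / m
        else:
            integral = b / m + (tp - a0 * b / m) * math.log((a0 + m) / a0) / m
        aupr += (b / n_pos) * integral
        t_grid = np.linspace(0.0, 1.0, 101)[1:]
        tail = [
            ((tp + t * b) / n_pos, (tp + t * b) / (a0 + t * m))
            for t in t_grid
        ]
        pr_arr = np.vstack([pr_arr, tail])
    return EvalResult(
        aupr=aupr,
        auroc=auroc,
        roc_points=roc_arr,
        pr_points=pr_arr,
        top_k=top_k,
        confusion=confusion,
    )


# ---------------------------------------------------------------------------
# directionality


def evaluate_directionality(pdag: PDAG | RankedEdgeList, gold: GoldStandard) -> DirectionalityCounts:
    """Directionality bookkeeping for a partially directed prediction.

    Accepts either a :class:`~grninfer.plpc.PDAG` or an undirected
    :class:`RankedEdgeList` whose metadata carries orientation marks.
    The gold standard must be directed; only its positive edges matter.
    """
    if not gold.directed:
        raise ValueError("directionality evaluation needs a directed gold standard")
    if isinstance(pdag, PDAG):
        items = []
        for i, j in pdag.edges():
            items.append(((pdag.gene_ids[i], pdag.gene_ids[j]), pdag.orientation(i, j)))
    else:
        items = []
        for k, (a, b, _) in enumerate(pdag):
            items.append(((a, b), pdag.meta[k].get("orientation")))

    pos = gold.positives
    n_edges = len(items)
    n_directed = 0
    n_tp = 0
    n_tp_correct = 0
    n_tp_directed = 0
    for (a, b), orient in items:
        directed_pair = None
        if orient == "forward":
            directed_pair = (a, b)
        elif orient == "backward":
            directed_pair = (b, a)
        if directed_pair is not None:
            n_directed += 1
        skeleton_hit = (a, b) in pos or (b, a) in pos
        if skeleton_hit:
            n_tp += 1
            if directed_pair is not None:
                n_tp_directed += 1
                if directed_pair in pos:
                    n_tp_correct += 1
    if n_directed == 0:
        return DirectionalityCounts(n_edges, 0, n_tp, 0, 0.0, 0, degenerate=True)
    return DirectionalityCounts(
        n_edges, n_directed, n_tp, n_tp_correct, n_tp_correct / n_directed, n_tp_directed
    )
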