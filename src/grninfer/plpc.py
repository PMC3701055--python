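"""Bounded-order, order-independent constraint-based causal network learning.

The PLPC estimator learns a partially directed network in three phases:

1. **Skeleton** — start from the complete undirected graph and, for each
   conditioning-set size l = 0..max_order, test every currently adjacent
   pair (i, j) for conditional independence given subsets S of size l drawn
   from the *frozen* adjacency sets of this level (the PC-stable discipline:
   deletions are applied only after a level completes, which makes the
   result independent of gene ordering and of how the pair list is
   partitioned across workers).  Conditional independence is decided by the
   Fisher-z test on Gaussian partial correlations.
2. **V-structures** — every unshielded triple i - k - j with k outside the
   recorded separating set of (i, j) is oriented i -> k <- j.
3. **Meek rules** — deterministic propagation rules applied to a fixpoint,
   never creating new v-structures or directed cycles.

Bounding the conditioning-set size ("low order") is what makes the search
tractable for thousands of genes; with max_order at least the maximum
vertex degree the bound is never active and the algorithm coincides with
unrestricted PC-stable.

Edge confidence for ranking and Borda integration is 1 - pmax, where pmax
is the largest p-value observed across a surviving pair's CI tests: an edge
that never came close to removal scores near 1.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Callable

import numpy as np
from joblib import Parallel, delayed
from scipy import stats

from ._utils import logger
from .base import BaseNetworkInference, as_expression
from .datatypes import ExpressionMatrix, RankedEdgeList

__all__ = [
    "PLPC",
    "Skeleton",
    "PDAG",
    "fisher_z_ci_test",
    "partial_correlation",
    "plpc_skeleton",
    "orient_v_structures",
    "apply_meek_rules",
    "plpc",
]

Pair = tuple[int, int]


# ---------------------------------------------------------------------------
# CI machinery


def fisher_z_ci_test(r: float, n: int, k: int, alpha: float) -> tuple[bool, float]:
    """Fisher-z conditional-independence test for a partial correlation.

    z = 0.5 ln((1+r)/(1-r)); sqrt(n-k-3)*|z| is approximately standard
    normal under independence given a conditioning set of size k.  Returns
    (independent, p-value); independent iff p > alpha.

    When n - k - 3 <= 0 the test is undecidable; conservative practice is
    to keep the edge, so the caller receives (False, 0.0) and a log entry.
    """
    if n - k - 3 <= 0:
        logger.warning("fisher_z_ci_test: n-k-3 <= 0 (n=%d, k=%d); edge retained", n, k)
        return False, 0.0
    r = float(np.clip(r, -1 + 1e-15, 1 - 1e-15))
    z = 0.5 * np.log((1 + r) / (1 - r))
    stat = np.sqrt(n - k - 3) * abs(z)
    pvalue = float(2 * stats.norm.sf(stat))
    return pvalue > alpha, pvalue


def partial_correlation(corr: np.ndarray, i: int, j: int, S: tuple[int, ...]) -> float:
    """Partial correlation of variables i, j given the set S, from the
    inverse of the correlation submatrix on {i, j} | S."""
    if i in S or j in S:
        raise ValueError("conditioning set must exclude i and j")
    if not S:
        return float(corr[i, j])
    idx = [i, j, *S]
    sub = corr[np.ix_(idx, idx)]
    try:
        omega = np.linalg.inv(sub)
    except np.linalg.LinAlgError:
        logger.warning("partial_correlation: singular submatrix for (%d, %d | %s); pseudo-inverse", i, j, S)
        omega = np.linalg.pinv(sub)
    denom = np.sqrt(omega[0, 0] * omega[1, 1])
    if denom == 0:
        return 0.0
    return float(np.clip(-omega[0, 1] / denom, -1.0, 1.0))


# ---------------------------------------------------------------------------
# graph containers


@dataclass
class Skeleton:
    """Undirected adjacency plus the book-keeping the orientation phase needs:
    the separating set recorded for each removed pair and, for surviving
    pairs, the largest p-value seen across their CI tests."""

    gene_ids: list[str]
    adj: list[set[int]]
    sepset: dict[Pair, tuple[int, ...]] = field(default_factory=dict)
    pmax: dict[Pair, float] = field(default_factory=dict)

    def edges(self) -> list[Pair]:
        return sorted((i, j) for i in range(len(self.adj)) for j in self.adj[i] if i < j)

    def has_edge(self, i: int, j: int) -> bool:
        return j in self.adj[i]


@dataclass
class PDAG:
    """Skeleton plus orientation marks: ``directed`` holds ordered pairs
    (i, j) meaning i -> j; skeleton edges absent from it are undirected."""

    gene_ids: list[str]
    adj: list[set[int]]
    directed: set[Pair] = field(default_factory=set)
    sepset: dict[Pair, tuple[int, ...]] = field(default_factory=dict)
    pmax: dict[Pair, float] = field(default_factory=dict)

    def edges(self) -> list[Pair]:
        return sorted((i, j) for i in range(len(self.adj)) for j in self.adj[i] if i < j)

    def orientation(self, i: int, j: int):
        """'forward' (i->j), 'backward' (j->i) or None for edge {i, j}."""
        if (i, j) in self.directed:
            return "forward"
        if (j, i) in self.directed:
            return "backward"
        return None

    def oriented_pairs(self) -> set[tuple[str, str]]:
        return {(self.gene_ids[i], self.gene_ids[j]) for i, j in self.directed}


# ---------------------------------------------------------------------------
# skeleton phase


def _gaussian_ci(corr: np.ndarray, n: int, alpha: float) -> Callable:
    def test(i: int, j: int, S: tuple[int, ...]) -> tuple[bool, float]:
        r = partial_correlation(corr, i, j, S)
        return fisher_z_ci_test(r, n, len(S), alpha)

    return test


def _test_pair(i, j, frozen_adj, level, ci_test):
    """All level-``level`` CI tests for one adjacent pair, against the frozen
    adjacencies.  Returns (removed, sepset-or-None, pmax over tests run).

    Conditioning sets are drawn from adj(i)\\{j} and adj(j)\\{i}; the smaller
    side is enumerated first, subsets in lexicographic order — this fixes
    which separating set is recorded, while PC-stable guarantees the set of
    removed edges does not depend on it.
    """
    pmax = -1.0
    sides = sorted(
        [tuple(sorted(frozen_adj[i] - {j})), tuple(sorted(frozen_adj[j] - {i}))], key=len
    )
    seen: set[tuple[int, ...]] = set()
    for side in sides:
        if len(side) < level:
            continue
        for S in itertools.combinations(side, level):
            if S in seen:
                continue
            seen.add(S)
            independent, p = ci_test(i, j, S)
            pmax = max(pmax, p)
            if independent:
                return True, S, pmax
    return False, None, pmax


def plpc_skeleton(
    expr: ExpressionMatrix | np.ndarray | None,
    alpha: float = 0.01,
    max_order: int = 8,
    ci_test: Callable | None = None,
    gene_ids: list[str] | None = None,
    n_nodes: int | None = None,
    n_jobs: int = 1,
) -> Skeleton:
    """Level-synchronous (PC-stable) bounded-order skeleton search.

    Either ``expr`` is given (Gaussian Fisher-z CI tests on its correlation
    matrix) or an explicit ``ci_test(i, j, S) -> (independent, p)`` callable
    with ``n_nodes``/``gene_ids`` — the latter is how an exact d-separation
    oracle is plugged in for testing.
    """
    if expr is not None:
        expr = as_expression(expr)
        # canonical gene order (sorted ids): the skeleton is order-independent
        # by PC-stable, and this also pins down the recorded sepsets — and
        # hence the v-structures — for any permutation of the input genes
        order = sorted(range(expr.n_genes), key=expr.gene_ids.__getitem__)
        gene_ids = [expr.gene_ids[k] for k in order]
        n_nodes = expr.n_genes
        if expr.n_samples <= max_order + 3:
            logger.warning(
                "plpc: n_samples=%d too small for max_order=%d; high orders will be skipped",
                expr.n_samples,
                max_order,
            )
        corr = np.corrcoef(expr.values[order])
        corr = np.nan_to_num(corr, nan=0.0)
        np.fill_diagonal(corr, 1.0)
        ci_test = _gaussian_ci(corr, expr.n_samples, alpha)
    if ci_test is None or n_nodes is None:
        raise ValueError("need either expr or (ci_test, n_nodes)")
    if gene_ids is None:
        gene_ids = [f"g{i}" for i in range(n_nodes)]

    adj = [set(range(n_nodes)) - {i} for i in range(n_nodes)]
    sepset: dict[Pair, tuple[int, ...]] = {}
    pmax: dict[Pair, float] = {}

    for level in range(max_order + 1):
        frozen = [set(a) for a in adj]  # PC-stable: freeze adjacencies for the level
        pairs = [(i, j) for i in range(n_nodes) for j in frozen[i] if i < j]
        testable = [
            (i, j)
            for i, j in pairs
            if len(frozen[i] - {j}) >= level or len(frozen[j] - {i}) >= level
        ]
        if not testable:
            break
        results = Parallel(n_jobs=n_jobs)(
            delayed(_test_pair)(i, j, frozen, level, ci_test) for i, j in testable
        )
        for (i, j), (removed, S, p) in zip(testable, results):
            if p >= 0:
                pmax[(i, j)] = max(pmax.get((i, j), 0.0), p)
            if removed:
                adj[i].discard(j)
                adj[j].discard(i)
                sepset[(i, j)] = S
    # pmax is meaningful only for surviving pairs
    pmax = {(i, j): p for (i, j), p in pmax.items() if j in adj[i]}
    return Skeleton(gene_ids, adj, sepset, pmax)


# ---------------------------------------------------------------------------
# orientation phase


def orient_v_structures(skel: Skeleton) -> PDAG:
    """Orient unshielded colliders: for each i - k - j with i, j non-adjacent,
    set i -> k <- j iff k is not in the recorded separating set of (i, j).

    Conflicting orientations from overlapping v-structures would leave an
    edge directed both ways; such edges are reverted to undirected and the
    conflict logged (conservative resolution).
    """
    n = len(skel.adj)
    votes: set[Pair] = set()
    for k in range(n):
        for i, j in itertools.combinations(sorted(skel.adj[k]), 2):
            if skel.has_edge(i, j):
                continue  # shielded
            key = (min(i, j), max(i, j))
            S = skel.sepset.get(key, ())
            if k not in S:
                votes.add((i, k))
                votes.add((j, k))
    directed = set()
    for a, b in votes:
        if (b, a) in votes:
            logger.warning(
                "orient_v_structures: conflicting orientation for %s-%s; left undirected",
                skel.gene_ids[min(a, b)],
                skel.gene_ids[max(a, b)],
            )
            continue
        directed.add((a, b))
    return PDAG(skel.gene_ids, [set(a) for a in skel.adj], directed, dict(skel.sepset), dict(skel.pmax))


def apply_meek_rules(pdag: PDAG) -> PDAG:
    """Propagate orientations with Meek's rules R1-R4 to a fixpoint.

    R1: a -> b - c, a and c non-adjacent            =>  b -> c
    R2: a -> c -> b with a - b                      =>  a -> b
    R3: a - b, a - c, a - d, c -> b, d -> b,
        c and d non-adjacent                        =>  a -> b
    R4: a - b, a - c, a and d adjacent, c -> d,
        d -> b, c and b non-adjacent                =>  a -> b
        (R4 cannot fire from v-structure initialization alone; it is kept
        for completeness and for externally supplied orientations.)

    A rule never overrides an existing orientation, so no edge ends up
    directed both ways and no new v-structure is created.
    """
    n = len(pdag.adj)
    adj = pdag.adj
    directed = set(pdag.directed)

    def und(a, b):
        return b in adj[a] and (a, b) not in directed and (b, a) not in directed

    def orient(a, b):
        if (b, a) in directed or (a, b) in directed:
            return False
        directed.add((a, b))
        return True

    changed = True
    while changed:
        changed = False
        for b in range(n):
            for c in sorted(adj[b]):
                if not und(b, c):
                    continue
                # R1: a -> b - c with a, c non-adjacent
                if any((a, b) in directed and c not in adj[a] and a != c for a in adj[b]):
                    changed |= orient(b, c)
                    continue
                # R2: b -> k -> c with b - c
                if any((b, k) in directed and (k, c) in directed for k in adj[b] & adj[c]):
                    changed |= orient(b, c)
                    continue
                # R3: b - c, b - d1, b - d2, d1 -> c, d2 -> c, d1, d2 non-adjacent
                parents = [d for d in adj[b] & adj[c] if und(b, d) and (d, c) in directed]
                if any(
                    d2 not in adj[d1]
                    for d1, d2 in itertools.combinations(parents, 2)
                ):
                    changed |= orient(b, c)
                    continue
                # R4: b - c, b - k, b adj d, k -> d, d -> c, k, c non-adjacent
                for k in sorted(adj[b]):
                    if not und(b, k):
                        continue
                    if any(
                        (k, d) in directed and (d, c) in directed and c not in adj[k]
                        for d in adj[b]
                    ):
                        changed |= orient(b, c)
                        break
    return PDAG(pdag.gene_ids, [set(a) for a in adj], directed, dict(pdag.sepset), dict(pdag.pmax))


# ---------------------------------------------------------------------------
# estimator


class PLPC(BaseNetworkInference):
    """Parallel low-order PC: bounded-order PC-stable causal structure
    learning with Fisher-z CI tests.

    Parameters
    ----------
    alpha : significance level of the CI tests (default 0.01); smaller
        values remove more edges.
    max_order : largest conditioning-set size tested (default 8).  Runtime
        grows steeply with it; with max_order >= the true maximum degree it
        is never binding.
    n_jobs : worker count for the per-pair CI tests within a level; the
        result is identical for any value (level-synchronous deletions).

    Fitted attributes: ``skeleton_``, ``pdag_`` and ``ranked_edges_`` —
    skeleton edges scored by 1 - pmax with the orientation stored as edge
    metadata.
    """

    def __init__(self, alpha: float = 0.01, max_order: int = 8, n_jobs: int = 1):
        self.alpha = alpha
        self.max_order = max_order
        self.n_jobs = n_jobs

    def fit(self, X, y=None):
        if not (0 < self.alpha < 1):
            raise ValueError(f"alpha must be in (0, 1), got {self.alpha}")
        if self.max_order < 0:
            raise ValueError(f"max_order must be >= 0, got {self.max_order}")
        expr = as_expression(X)
        self._set_fitted_meta(expr)
        skel = plpc_skeleton(expr, alpha=self.alpha, max_order=self.max_order, n_jobs=self.n_jobs)
        self.skeleton_ = skel
        pdag = apply_meek_rules(orient_v_structures(skel))
        self.pdag_ = pdag
        edges, meta = [], []
        for i, j in pdag.edges():
            score = 1.0 - pdag.pmax.get((i, j), 0.0)
            gi, gj = pdag.gene_ids[i], pdag.gene_ids[j]
            orient = pdag.orientation(i, j)
            if gi > gj:  # keep the mark consistent with canonical pair order
                gi, gj = gj, gi
                orient = {"forward": "backward", "backward": "forward", None: None}[orient]
            edges.append((gi, gj, score))
            meta.append({"orientation": orient})
        self.ranked_edges_ = RankedEdgeList(edges, directed=False, method_tag="plpc", meta=meta)
        return self


def plpc(expr, alpha: float = 0.01, max_order: int = 8, n_jobs: int = 1) -> tuple[PDAG, RankedEdgeList]:
    est = PLPC(alpha=alpha, max_order=max_order, n_jobs=n_jobs).fit(expr)
    return est.pdag_, est.ranked_edges_
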