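"""Independent reference implementations used only as test oracles.

Everything here is deliberately written by the most naive route available
(recursion, exhaustive enumeration, brute force over orientations) and
shares no code with the package implementation it checks.
"""

from __future__ import annotations

import itertools

import networkx as nx
import numpy as np


def recursive_pcor(corr: np.ndarray, i: int, j: int, S: tuple[int, ...]) -> float:
    """Partial correlation by the textbook recursion on the conditioning set."""
    if not S:
        return corr[i, j]
    k, rest = S[0], tuple(S[1:])
    r_ij = recursive_pcor(corr, i, j, rest)
    r_ik = recursive_pcor(corr, i, k, rest)
    r_jk = recursive_pcor(corr, j, k, rest)
    return (r_ij - r_ik * r_jk) / np.sqrt((1 - r_ik**2) * (1 - r_jk**2))


def exhaustive_auc(scored: list[tuple[float, int]]) -> tuple[float, float]:
    """AUROC and AUPR by enumerating every threshold of a fully scored
    universe (list of (score, 0/1 label)); trapezoidal integration with the
    recall-0 point anchored at the first achieved precision."""
    n_pos = sum(l for _, l in scored)
    n_neg = len(scored) - n_pos
    order = sorted(scored, key=lambda t: -t[0])
    thresholds = sorted({s for s, _ in scored}, reverse=True)
    roc = [(0.0, 0.0)]
    pr = []
    for thr in thresholds:
        tp = sum(1 for s, l in order if s >= thr and l == 1)
        fp = sum(1 for s, l in order if s >= thr and l == 0)
        roc.append((fp / n_neg, tp / n_pos))
        pr.append((tp / n_pos, tp / (tp + fp)))
    pr = [(0.0, pr[0][1])] + pr

    def trap(pts):
        area = 0.0
        for (x0, y0), (x1, y1) in zip(pts, pts[1:]):
            area += (x1 - x0) * (y0 + y1) / 2
        return area

    return trap(roc), trap(pr)


def dsep_ci_test(dag: nx.DiGraph):
    """Exact conditional-independence oracle from d-separation in a DAG."""

    def test(i, j, S):
        indep = nx.is_d_separator(dag, {i}, {j}, set(S))
        return indep, (1.0 if indep else 0.0)

    return test


def naive_pc_stable(n_nodes: int, ci_test, max_order: int):
    """Bare-bones PC-stable skeleton: returns (set of frozenset edges,
    sepset dict).  Written independently of the package implementation."""
    adj = {i: set(range(n_nodes)) - {i} for i in range(n_nodes)}
    sepset = {}
    for level in range(max_order + 1):
        frozen = {i: set(a) for i, a in adj.items()}
        removals = []
        for i in range(n_nodes):
            for j in frozen[i]:
                if j < i or j not in adj[i]:
                    continue
                found = False
                for side in (frozen[i] - {j}, frozen[j] - {i}):
                    for S in itertools.combinations(sorted(side), level):
                        if ci_test(i, j, S)[0]:
                            removals.append((i, j, S))
                            found = True
                            break
                    if found:
                        break
        for i, j, S in removals:
            adj[i].discard(j)
            adj[j].discard(i)
            sepset[frozenset((i, j))] = set(S)
    edges = {frozenset((i, j)) for i in adj for j in adj[i]}
    return edges, sepset


def cpdag_compelled_edges(dag: nx.DiGraph) -> tuple[set, set]:
    """CPDAG of a DAG by brute force: enumerate all orientations of the
    skeleton that are acyclic and preserve the v-structures, and mark an
    edge compelled iff every member of the class orients it the same way.

    Returns (directed_edges, undirected_frozenset_pairs).  Exponential in
    the edge count; fine for the <= 10-edge graphs used in tests.
    """
    skeleton = [tuple(sorted(e)) for e in dag.to_undirected().edges()]

    def vstructs(g: nx.DiGraph):
        out = set()
        for k in g.nodes:
            for a, b in itertools.combinations(sorted(g.predecessors(k)), 2):
                if not (g.has_edge(a, b) or g.has_edge(b, a)):
                    out.add((a, k, b))
        return out

    target_v = vstructs(dag)
    members = []
    for bits in itertools.product([0, 1], repeat=len(skeleton)):
        g = nx.DiGraph()
        g.add_nodes_from(dag.nodes)
        for (a, b), bit in zip(skeleton, bits):
            g.add_edge(a, b) if bit == 0 else g.add_edge(b, a)
        if nx.is_directed_acyclic_graph(g) and vstructs(g) == target_v:
            members.append(g)
    assert members, "equivalence class enumeration found no member"
    directed, undirected = set(), set()
    for a, b in skeleton:
        if all(g.has_edge(a, b) for g in members):
            directed.add((a, b))
        elif all(g.has_edge(b, a) for g in members):
            directed.add((b, a))
        else:
            undirected.add(frozenset((a, b)))
    return directed, undirected


def random_dag(rng: np.random.Generator, n_nodes: int, p_edge: float) -> nx.DiGraph:
    """Random DAG with edges oriented low index -> high index."""
    g = nx.DiGraph()
    g.add_nodes_from(range(n_nodes))
    for i in range(n_nodes):
        for j in range(i + 1, n_nodes):
            if rng.random() < p_edge:
                g.add_edge(i, j)
    return g


def gaussian_sem_sample(dag: nx.DiGraph, n: int, rng: np.random.Generator, noise_sd: float = 0.5):
    """Draw n samples from a linear-Gaussian SEM on the DAG (weights
    uniform in +-[0.5, 1.5])."""
    nodes = list(nx.topological_sort(dag))
    weights = {e: rng.uniform(0.5, 1.5) * rng.choice([-1, 1]) for e in dag.edges}
    x = np.zeros((len(dag.nodes), n))
    for v in nodes:
        parents = list(dag.predecessors(v))
        if not parents:
            x[v] = rng.normal(0, 1, n)
        else:
            x[v] = sum(weights[(p, v)] * x[p] for p in parents) + rng.normal(0, noise_sd, n)
    return x
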