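"""Known-truth synthetic benchmarks for every inference algorithm.

A random directed acyclic network over genes (only transcription factors
have outgoing edges) drives a linear-Gaussian structural equation model at
steady state: each sample is drawn by ancestral sampling,

    x_g = sum_parents w_pg * x_p + eps_g,   eps_g ~ N(0, sigma^2),

with root nodes standard normal.  This keeps exactly the statistical
structure the implemented methods assume (linear effects, additive Gaussian
noise) while staying dependency-free and fast; it deliberately does not
model kinetic/ODE dynamics, saturation or experimental perturbations.

Defaults define the toolkit's standard benchmark condition: 50 genes,
20 TFs, 200 samples, mean TF out-degree 2, effect sizes |w| in [0.5, 1]
with random sign, noise sd 0.5.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .datatypes import ExpressionMatrix, GoldStandard

__all__ = [
    "SyntheticSpec",
    "WeightedDAG",
    "SyntheticDataset",
    "generate_dag",
    "simulate_expression",
    "export_gold",
    "make_dataset",
    "sem_covariance",
]


@dataclass
class SyntheticSpec:
    """Parameters of one synthetic benchmark instance.

    Either ``edge_density`` (probability per admissible TF->gene pair) or
    ``mean_out_degree`` (expected out-edges per TF, the default dial)
    controls sparsity.  Genes are indexed in topological order with the
    ``n_tfs`` transcription factors first, so acyclicity and the
    TF-only-regulators rule hold by construction; the weight matrix of a
    DAG is nilpotent, hence its spectral radius is 0.
    """

    n_genes: int = 50
    n_tfs: int = 20
    n_samples: int = 200
    topology: str = "erdos_renyi"
    mean_out_degree: float = 2.0
    edge_density: float | None = None
    w_min: float = 0.5
    w_max: float = 1.0
    noise_sd: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0 < self.n_tfs <= self.n_genes):
            raise ValueError("need 0 < n_tfs <= n_genes")
        if self.topology not in ("erdos_renyi", "scale_free_out"):
            raise ValueError(f"unknown topology {self.topology!r}")
        if not (0 <= self.w_min <= self.w_max):
            raise ValueError("need 0 <= w_min <= w_max")


@dataclass
class WeightedDAG:
    """True network: gene ids, TF ids, and a weight matrix with
    weights[p, g] != 0 meaning p regulates g (p always a TF, p's index
    below g's)."""

    gene_ids: list[str]
    tf_ids: list[str]
    weights: np.ndarray

    def edges(self) -> list[tuple[str, str, float]]:
        ps, gs = np.nonzero(self.weights)
        return [
            (self.gene_ids[p], self.gene_ids[g], float(self.weights[p, g]))
            for p, g in zip(ps, gs)
        ]

    @property
    def n_edges(self) -> int:
        return int(np.count_nonzero(self.weights))

    def max_degree(self) -> int:
        und = (self.weights != 0) | (self.weights != 0).T
        return int(und.sum(axis=0).max(initial=0))


@dataclass
class SyntheticDataset:
    expression: ExpressionMatrix
    tf_ids: list[str]
    gold: GoldStandard
    dag: WeightedDAG
    spec: SyntheticSpec = field(repr=False, default=None)


def _gene_ids(n: int) -> list[str]:
    width = max(3, len(str(n)))
    return [f"G{i + 1:0{width}d}" for i in range(n)]


def generate_dag(spec: SyntheticSpec) -> WeightedDAG:
    """Sample a random weighted DAG under the spec's topology.

    erdos_renyi: every admissible pair (TF index i -> gene index j > i)
    is an edge independently with probability ``edge_density`` (or the
    probability matching ``mean_out_degree``).  scale_free_out: per-TF
    out-degrees follow a heavy-tailed (Zipf) draw rescaled to the same
    expected edge count, producing hub regulators.
    """
    rng = np.random.default_rng(spec.seed)
    n, m = spec.n_genes, spec.n_tfs
    gene_ids = _gene_ids(n)
    tf_ids = gene_ids[:m]
    weights = np.zeros((n, n))
    admissible = [(i, j) for i in range(m) for j in range(i + 1, n)]
    if spec.edge_density is not None:
        p_edge = float(spec.edge_density)
    else:
        p_edge = min(1.0, spec.mean_out_degree * m / max(1, len(admissible)))
    if spec.topology == "erdos_renyi":
        mask = rng.random(len(admissible)) < p_edge
        chosen = [pair for pair, keep in zip(admissible, mask) if keep]
    else:
        expected_total = p_edge * len(admissible)
        raw = rng.zipf(2.0, size=m).astype(float)
        scaled = raw * expected_total / raw.sum()
        chosen = []
        for i in range(m):
            avail = n - 1 - i
            base = int(scaled[i])
            k = base + (1 if rng.random() < scaled[i] - base else 0)
            k = min(avail, k)
            if k > 0:
                targets = rng.choice(np.arange(i + 1, n), size=k, replace=False)
                chosen.extend((i, int(j)) for j in targets)
    for i, j in chosen:
        w = rng.uniform(spec.w_min, spec.w_max)
        if rng.random() < 0.5:
            w = -w
        weights[i, j] = w
    return WeightedDAG(gene_ids, tf_ids, weights)


def simulate_expression(dag: WeightedDAG, spec: SyntheticSpec) -> ExpressionMatrix:
    """Ancestral sampling of i.i.d. steady-state samples from the SEM.

    Root genes are standard normal; every regulated gene is the weighted
    sum of its parents plus N(0, noise_sd^2) noise.  The same spec seed
    always yields the same matrix (offset from the topology stream so the
    graph and the noise are independently reproducible).
    """
    rng = np.random.default_rng((int(spec.seed) + 1_000_003) % 2**31)
    n, s = len(dag.gene_ids), spec.n_samples
    w = dag.weights
    x = np.zeros((n, s))
    has_parents = (w != 0).any(axis=0)
    for g in range(n):  # gene index order is topological
        if not has_parents[g]:
            x[g] = rng.normal(0.0, 1.0, size=s)
        else:
            x[g] = w[:, g] @ x + rng.normal(0.0, spec.noise_sd, size=s)
    sample_ids = [f"S{k + 1:03d}" for k in range(s)]
    return ExpressionMatrix(list(dag.gene_ids), sample_ids, x)


def sem_covariance(dag: WeightedDAG, noise_sd: float) -> np.ndarray:
    """Closed-form covariance of the SEM: with x = W^T x + eps,
    Sigma = (I - W^T)^-1 D (I - W^T)^-T, D the per-gene noise variances
    (1 for roots, noise_sd^2 otherwise)."""
    n = len(dag.gene_ids)
    w = dag.weights
    has_parents = (w != 0).any(axis=0)
    d = np.where(has_parents, noise_sd**2, 1.0)
    a = np.linalg.inv(np.eye(n) - w.T)
    return a @ np.diag(d) @ a.T


def export_gold(
    dag: WeightedDAG, n_negatives: int | str = "all", seed: int = 0
) -> GoldStandard:
    """Directed gold standard: every true edge labeled 1, negatives drawn
    uniformly (without replacement) from unregulating TF->gene pairs — the
    same evaluable universe the inference methods search."""
    positives = {(a, b) for a, b, _ in dag.edges()}
    candidates = sorted(
        (tf, g)
        for tf in dag.tf_ids
        for g in dag.gene_ids
        if tf != g and (tf, g) not in positives
    )
    if n_negatives == "all":
        negatives = candidates
    else:
        n_negatives = int(n_negatives)
        if n_negatives > len(candidates):
            raise ValueError(f"only {len(candidates)} non-edges available")
        rng = np.random.default_rng(seed)
        idx = rng.choice(len(candidates), size=n_negatives, replace=False)
        negatives = [candidates[k] for k in sorted(idx)]
    labels = {p: 1 for p in positives}
    labels.update({p: 0 for p in negatives})
    return GoldStandard(labels, directed=True)


def make_dataset(spec: SyntheticSpec | None = None, **kwargs) -> SyntheticDataset:
    """Generate a full benchmark instance: DAG, expression, TF list, gold."""
    if spec is None:
        spec = SyntheticSpec(**kwargs)
    dag = generate_dag(spec)
    expr = simulate_expression(dag, spec)
    gold = export_gold(dag, "all", seed=spec.seed)
    return SyntheticDataset(expr, list(dag.tf_ids), gold, dag, spec)
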