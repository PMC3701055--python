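"""End-to-end synthetic benchmark: generate -> infer -> integrate -> evaluate.

This is the toolkit's smoke test and the computation behind the acceptance
script: on known-truth synthetic networks (default condition: 50 genes,
20 TFs, 200 samples, mean out-degree 2, noise sd 0.5) every algorithm is
run over several seeds and scored by AUROC/AUPR against the full
TF x gene gold standard; the Borda composite of the three best-performing
methods and a gene-label-shuffle control are evaluated the same way, and
PLPC's orientation accuracy among its true-positive edges is tallied.

Desk-scale settings (100 trees, 100 resamples, conditioning order 3) keep a
10-seed run in the low minutes on one CPU while leaving each method's
reference defaults untouched for real analyses.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ._utils import derive_seed
from .datatypes import ExpressionMatrix
from .ensemble import DirectionalityCounts, borda_integrate, evaluate_auc, evaluate_directionality
from .pairwise import CLRNetwork, GGMNetwork, RelevanceNetwork
from .plpc import PLPC
from .regression import GENIE3, TIGRESS
from .synthetic import SyntheticSpec, make_dataset

__all__ = ["BenchmarkResult", "run_benchmark", "shuffle_gene_labels"]

METHODS = ("rn", "ggm", "clr", "genie3", "tigress", "plpc")


@dataclass
class BenchmarkResult:
    auroc: pd.DataFrame  # rows: seeds; columns: methods, composite, shuffle
    aupr: pd.DataFrame
    composite_members: tuple[str, ...]
    composite_wins: int  # seeds where composite AUROC >= median of its members
    n_seeds: int
    direction: DirectionalityCounts  # PLPC counts pooled over seeds
    per_seed_direction: list[DirectionalityCounts] = field(default_factory=list)

    @property
    def mean_auroc(self) -> dict[str, float]:
        return {c: float(self.auroc[c].mean()) for c in self.auroc.columns}

    @property
    def orientation_accuracy(self) -> float:
        """Fraction of PLPC's oriented true-positive edges pointing the
        right way (pooled over seeds)."""
        d = self.direction
        return d.n_tp_correct_direction / d.n_tp_directed if d.n_tp_directed else float("nan")


def shuffle_gene_labels(expr: ExpressionMatrix, seed: int) -> ExpressionMatrix:
    """Random permutation of gene identifiers — the negative control that
    breaks every gene-to-gold association while preserving the data."""
    rng = np.random.default_rng(seed)
    perm = rng.permutation(expr.n_genes)
    ids = [expr.gene_ids[k] for k in perm]
    return ExpressionMatrix(ids, list(expr.sample_ids), expr.values.copy())


def _estimators(seed: int, tf_ids, n_trees: int, n_resamples: int, plpc_order: int, n_jobs: int):
    return {
        "rn": RelevanceNetwork(emit_all=True),
        "ggm": GGMNetwork(),
        "clr": CLRNetwork(),
        "genie3": GENIE3(n_trees=n_trees, tf_ids=tf_ids, random_state=seed, n_jobs=n_jobs),
        "tigress": TIGRESS(
            n_resamples=n_resamples, tf_ids=tf_ids, random_state=seed, n_jobs=n_jobs
        ),
        "plpc": PLPC(alpha=0.01, max_order=plpc_order, n_jobs=n_jobs),
    }


def run_benchmark(
    n_seeds: int = 10,
    base_seed: int = 0,
    spec_kwargs: dict | None = None,
    n_trees: int = 100,
    n_resamples: int = 100,
    plpc_order: int = 3,
    n_jobs: int = 1,
    methods: tuple[str, ...] = METHODS,
) -> BenchmarkResult:
    """Run the full pipeline over ``n_seeds`` independent networks.

    Per seed: one synthetic dataset, all requested algorithms, AUC
    evaluation on the complete TF x gene universe, the Borda composite of
    the three methods with the best mean AUROC, and a label-shuffle
    control (relevance network on gene-permuted data).
    """
    spec_kwargs = dict(spec_kwargs or {})
    auroc_rows, aupr_rows = [], []
    nets_per_seed: list[dict] = []
    golds = []
    dir_counts: list[DirectionalityCounts] = []
    seeds = [derive_seed(base_seed, "benchmark", k) for k in range(n_seeds)]
    for seed in seeds:
        ds = make_dataset(SyntheticSpec(seed=seed, **spec_kwargs))
        golds.append(ds.gold)
        row_roc, row_pr, nets = {}, {}, {}
        for name in methods:
            est = _estimators(seed, ds.tf_ids, n_trees, n_resamples, plpc_order, n_jobs)[name]
            net = est.fit_network(ds.expression)
            nets[name] = net
            res = evaluate_auc(net, ds.gold, top_k=100_000)
            row_roc[name], row_pr[name] = res.auroc, res.aupr
            if name == "plpc":
                dir_counts.append(evaluate_directionality(est.pdag_, ds.gold))
        shuffled = shuffle_gene_labels(ds.expression, derive_seed(seed, "shuffle"))
        res = evaluate_auc(
            RelevanceNetwork(emit_all=True).fit_network(shuffled), ds.gold, top_k=100_000
        )
        row_roc["shuffle"], row_pr["shuffle"] = res.auroc, res.aupr
        auroc_rows.append(row_roc)
        aupr_rows.append(row_pr)
        nets_per_seed.append(nets)

    auroc = pd.DataFrame(auroc_rows, index=seeds)
    aupr = pd.DataFrame(aupr_rows, index=seeds)

    mean_by_method = auroc[list(methods)].mean().sort_values(ascending=False)
    members = tuple(mean_by_method.index[:3])
    wins = 0
    comp_roc, comp_pr = [], []
    for k, seed in enumerate(seeds):
        composite = borda_integrate([nets_per_seed[k][m] for m in members], top_k=100_000)
        res = evaluate_auc(composite, golds[k], top_k=100_000)
        comp_roc.append(res.auroc)
        comp_pr.append(res.aupr)
        if res.auroc >= float(np.median([auroc.loc[seed, m] for m in members])):
            wins += 1
    auroc["composite"] = comp_roc
    aupr["composite"] = comp_pr

    pooled = DirectionalityCounts(
        n_edges=sum(d.n_edges for d in dir_counts),
        n_directed=sum(d.n_directed for d in dir_counts),
        n_tp=sum(d.n_tp for d in dir_counts),
        n_tp_correct_direction=sum(d.n_tp_correct_direction for d in dir_counts),
        directed_precision=(
            sum(d.n_tp_correct_direction for d in dir_counts)
            / max(1, sum(d.n_directed for d in dir_counts))
        ),
        n_tp_directed=sum(d.n_tp_directed for d in dir_counts),
    ) if dir_counts else DirectionalityCounts(0, 0, 0, 0, 0.0, 0, degenerate=True)

    return BenchmarkResult(
        auroc=auroc,
        aupr=aupr,
        composite_members=members,
        composite_wins=wins,
        n_seeds=n_seeds,
        direction=pooled,
        per_seed_direction=dir_counts,
    )
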