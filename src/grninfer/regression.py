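"""Per-target regression network inference: GENIE3 and TIGRESS.

Both methods decompose the network problem into one regression per target
gene (target expression ~ expression of candidate transcription factors)
and pool per-target scores into a directed TF->target edge ranking.

The decomposition is embarrassingly parallel.  Reproducibility for any
worker count is guaranteed by deriving each target's RNG seed from
(base seed, target id) with a cryptographic hash, so results depend only on
the configuration, never on scheduling order.
"""

from __future__ import annotations

import numpy as np
from joblib import Parallel, delayed
from sklearn.ensemble import ExtraTreesRegressor
from sklearn.linear_model import lars_path

from ._utils import derive_seed, logger
from .base import BaseNetworkInference, as_expression
from .datatypes import ExpressionMatrix, RankedEdgeList, match_tf_list

__all__ = ["GENIE3", "TIGRESS", "genie3", "tigress"]


def _resolve_tfs(expr: ExpressionMatrix, tf_ids) -> list[str]:
    if tf_ids is None:
        return list(expr.gene_ids)
    return match_tf_list(tf_ids, expr)


def _pool_edges(expr, tf_ids, per_target, tag) -> RankedEdgeList:
    """Assemble a directed edge list from per-target score vectors.

    Each target's scores are normalized to sum 1 (equal mass per target) so
    high-variance targets cannot dominate the global ranking.
    """
    edges = []
    for target, (cands, scores) in per_target.items():
        total = scores.sum()
        if total > 0:
            scores = scores / total
        for tf, s in zip(cands, scores):
            edges.append((tf, target, float(s)))
    return RankedEdgeList(edges, directed=True, method_tag=tag)


class GENIE3(BaseNetworkInference):
    """Tree-ensemble network inference.

    For each target gene an extremely-randomized-trees regressor is fit on
    the candidate TFs (excluding the target itself); the edge score of
    TF -> target is the TF's total variance-reduction importance, normalized
    per target.  Defaults follow the method's reference description:
    1000 trees, sqrt(p) candidate features per split.

    Parameters
    ----------
    n_trees : ensemble size per target (default 1000).
    candidate_fraction : "sqrt" or "all" — features considered per split.
    tf_ids : optional list of candidate regulators; default all genes.
    random_state : base seed; per-target seeds are derived from it.
    n_jobs : worker count; never changes the result.
    """

    def __init__(
        self,
        n_trees: int = 1000,
        candidate_fraction: str = "sqrt",
        tf_ids=None,
        random_state: int = 0,
        n_jobs: int = 1,
    ):
        self.n_trees = n_trees
        self.candidate_fraction = candidate_fraction
        self.tf_ids = tf_ids
        self.random_state = random_state
        self.n_jobs = n_jobs

    def _fit_target(self, x, gene_ids, tfs, target):
        cands = [t for t in tfs if t != target]
        gi = {g: k for k, g in enumerate(gene_ids)}
        y = x[gi[target]]
        if y.std() == 0:
            logger.warning("GENIE3: zero-variance target %s scored 0", target)
            return cands, np.zeros(len(cands))
        xmat = x[[gi[c] for c in cands]].T
        max_features = "sqrt" if self.candidate_fraction == "sqrt" else 1.0
        forest = ExtraTreesRegressor(
            n_estimators=self.n_trees,
            max_features=max_features,
            random_state=derive_seed(self.random_state, "genie3", target),
            n_jobs=1,
        )
        forest.fit(xmat, (y - y.mean()) / y.std())
        return cands, forest.feature_importances_

    def fit(self, X, y=None):
        if self.candidate_fraction not in ("sqrt", "all"):
            raise ValueError(f"candidate_fraction must be 'sqrt' or 'all', got {self.candidate_fraction!r}")
        expr = as_expression(X)
        self._set_fitted_meta(expr)
        tfs = _resolve_tfs(expr, self.tf_ids)
        self.tf_ids_ = tfs
        results = Parallel(n_jobs=self.n_jobs)(
            delayed(self._fit_target)(expr.values, expr.gene_ids, tfs, t) for t in expr.gene_ids
        )
        per_target = dict(zip(expr.gene_ids, results))
        self.importances_ = {t: dict(zip(c, s)) for t, (c, s) in per_target.items()}
        self.ranked_edges_ = _pool_edges(expr, tfs, per_target, "genie3")
        return self


class TIGRESS(BaseNetworkInference):
    """Stability-selection network inference with randomized LARS.

    For each target, ``n_resamples`` half-samples are drawn; on each, every
    candidate TF's column is rescaled by an independent Uniform[alpha, 1]
    weight and LARS is run for ``lars_steps`` steps.  The selection
    frequency of a TF within the first l steps, averaged over resamples,
    gives its stability score; "area" scoring averages the frequency over
    steps 1..L (the default), "frequency" uses step L alone.

    Defaults follow the method's reference description: R=1000 resamples,
    alpha=0.2, L=5 LARS steps, area scoring.
    """

    def __init__(
        self,
        n_resamples: int = 1000,
        lars_steps: int = 5,
        alpha: float = 0.2,
        scoring: str = "area",
        tf_ids=None,
        random_state: int = 0,
        n_jobs: int = 1,
    ):
        self.n_resamples = n_resamples
        self.lars_steps = lars_steps
        self.alpha = alpha
        self.scoring = scoring
        self.tf_ids = tf_ids
        self.random_state = random_state
        self.n_jobs = n_jobs

    def _fit_target(self, x, gene_ids, tfs, target):
        cands = [t for t in tfs if t != target]
        gi = {g: k for k, g in enumerate(gene_ids)}
        y = x[gi[target]].copy()
        p = len(cands)
        L = min(self.lars_steps, p)
        if L < self.lars_steps:
            logger.warning("TIGRESS: lars_steps clipped to %d for target %s", L, target)
        if y.std() == 0:
            return cands, np.zeros(p)
        xmat = x[[gi[c] for c in cands]].T.copy()
        # standardize once; per-resample randomization rescales columns
        xmat = (xmat - xmat.mean(axis=0)) / np.where(xmat.std(axis=0) == 0, 1.0, xmat.std(axis=0))
        y = (y - y.mean()) / y.std()
        n = len(y)
        half = n // 2
        rng = np.random.default_rng(derive_seed(self.random_state, "tigress", target))
        # sel_at_step[l, f]: number of resamples where feature f entered within l+1 steps
        sel = np.zeros((L, p))
        for _ in range(self.n_resamples):
            idx = rng.choice(n, size=half, replace=False)
            w = rng.uniform(self.alpha, 1.0, size=p)
            xr = xmat[idx] * w
            yr = y[idx]
            try:
                _, _, coefs = lars_path(xr, yr, max_iter=L, method="lar")
            except Exception:  # degenerate resample; contributes nothing
                continue
            nonzero = coefs != 0  # (p, n_steps+1)
            n_steps = nonzero.shape[1] - 1
            for l in range(L):
                step = min(l + 1, n_steps)
                sel[l] += nonzero[:, step]
        freq = sel / self.n_resamples
        scores = freq.mean(axis=0) if self.scoring == "area" else freq[-1]
        return cands, scores

    def fit(self, X, y=None):
        if self.scoring not in ("area", "frequency"):
            raise ValueError(f"scoring must be 'area' or 'frequency', got {self.scoring!r}")
        if not (0 < self.alpha <= 1):
            raise ValueError(f"alpha must be in (0, 1], got {self.alpha}")
        expr = as_expression(X)
        self._set_fitted_meta(expr)
        tfs = _resolve_tfs(expr, self.tf_ids)
        self.tf_ids_ = tfs
        results = Parallel(n_jobs=self.n_jobs)(
            delayed(self._fit_target)(expr.values, expr.gene_ids, tfs, t) for t in expr.gene_ids
        )
        per_target = dict(zip(expr.gene_ids, results))
        self.selection_frequencies_ = {t: dict(zip(c, s)) for t, (c, s) in per_target.items()}
        self.ranked_edges_ = _pool_edges(expr, tfs, per_target, "tigress")
        return self


def genie3(expr, tf_ids=None, n_trees: int = 1000, random_state: int = 0, n_jobs: int = 1) -> RankedEdgeList:
    return GENIE3(n_trees=n_trees, tf_ids=tf_ids, random_state=random_state, n_jobs=n_jobs).fit_network(expr)


def tigress(
    expr,
    tf_ids=None,
    n_resamples: int = 1000,
    lars_steps: int = 5,
    alpha: float = 0.2,
    scoring: str = "area",
    random_state: int = 0,
    n_jobs: int = 1,
) -> RankedEdgeList:
    est = TIGRESS(
        n_resamples=n_resamples,
        lars_steps=lars_steps,
        alpha=alpha,
        scoring=scoring,
        tf_ids=tf_ids,
        random_state=random_state,
        n_jobs=n_jobs,
    )
    return est.fit_network(expr)
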