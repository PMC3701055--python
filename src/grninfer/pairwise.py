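"""Pairwise network inference: relevance networks, shrinkage GGM, CLR.

Three classic families of gene-pair scoring:

* :class:`RelevanceNetwork` — Pearson co-expression with positive/negative
  thresholds.
* :class:`GGMNetwork` — graphical Gaussian model via an analytically shrunk
  correlation matrix (Schafer-Strimmer / Ledoit-Wolf style closed-form
  shrinkage intensity toward the identity), ranked by absolute partial
  correlation.
* :class:`CLRNetwork` — context likelihood of relatedness: mutual
  information z-scored against each gene's MI background, combined as
  sqrt(z_i^2 + z_j^2).

All three emit undirected :class:`~grninfer.datatypes.RankedEdgeList`
objects whose scores increase with confidence.
"""

from __future__ import annotations

import numpy as np
from scipy.interpolate import BSpline

from ._utils import logger
from .base import BaseNetworkInference, as_expression
from .datatypes import ExpressionMatrix, RankedEdgeList

__all__ = [
    "RelevanceNetwork",
    "GGMNetwork",
    "CLRNetwork",
    "clr_scores",
    "pearson_matrix",
    "mutual_information_matrix",
    "relevance_network",
    "ggm_network",
    "clr_network",
]


# ---------------------------------------------------------------------------
# correlation


def pearson_matrix(expr: ExpressionMatrix | np.ndarray) -> np.ndarray:
    """Pearson correlation between all gene pairs.

    Zero-variance genes cannot be correlated; their off-diagonal entries are
    set to 0 (logged) and the diagonal stays 1, so downstream thresholding
    simply never selects them.
    """
    expr = as_expression(expr)
    x = expr.values
    sd = x.std(axis=1)
    zero = sd == 0
    if zero.any():
        logger.warning("pearson_matrix: %d zero-variance gene(s) scored 0", int(zero.sum()))
    xc = x - x.mean(axis=1, keepdims=True)
    denom = np.where(zero, 1.0, sd * np.sqrt(x.shape[1]))
    xn = xc / denom[:, None]
    r = xn @ xn.T
    r[zero, :] = 0.0
    r[:, zero] = 0.0
    np.fill_diagonal(r, 1.0)
    return np.clip(r, -1.0, 1.0)


def _all_pairs(gene_ids, score_matrix, sign_matrix=None, tag=""):
    n = len(gene_ids)
    iu, ju = np.triu_indices(n, k=1)
    edges = [(gene_ids[i], gene_ids[j], float(score_matrix[i, j])) for i, j in zip(iu, ju)]
    meta = None
    if sign_matrix is not None:
        meta = [{"sign": int(np.sign(sign_matrix[i, j]))} for i, j in zip(iu, ju)]
    return RankedEdgeList(edges, directed=False, method_tag=tag, meta=meta)


class RelevanceNetwork(BaseNetworkInference):
    """Co-expression (relevance) network from thresholded Pearson correlation.

    Parameters
    ----------
    pos_threshold, neg_threshold:
        Keep a pair when r >= pos_threshold or r <= neg_threshold.  The
        defaults (0.9, -1.0) keep strong positive co-expression only: a
        negative threshold of exactly -1 excludes every anti-correlated
        pair short of perfect anti-correlation.
    emit_all:
        When true, ignore the thresholds and emit every pair scored by |r|
        (needed for rank integration and AUC evaluation, where truncation
        happens downstream).

    The edge score is |r|; the sign of r is kept as edge metadata.
    """

    def __init__(self, pos_threshold: float = 0.9, neg_threshold: float = -1.0, emit_all: bool = False):
        self.pos_threshold = pos_threshold
        self.neg_threshold = neg_threshold
        self.emit_all = emit_all

    def fit(self, X, y=None):
        if not (-1.0 <= self.neg_threshold <= self.pos_threshold <= 1.0):
            raise ValueError(
                "require -1 <= neg_threshold <= pos_threshold <= 1, got "
                f"({self.pos_threshold}, {self.neg_threshold})"
            )
        expr = as_expression(X)
        self._set_fitted_meta(expr)
        r = pearson_matrix(expr)
        self.correlation_ = r
        if self.emit_all:
            self.ranked_edges_ = _all_pairs(expr.gene_ids, np.abs(r), r, tag="rn")
        else:
            n = expr.n_genes
            iu, ju = np.triu_indices(n, k=1)
            keep = (r[iu, ju] >= self.pos_threshold) | (r[iu, ju] <= self.neg_threshold)
            edges, meta = [], []
            for i, j in zip(iu[keep], ju[keep]):
                edges.append((expr.gene_ids[i], expr.gene_ids[j], float(abs(r[i, j]))))
                meta.append({"sign": int(np.sign(r[i, j]))})
            if not edges:
                logger.warning("relevance network: all pairs filtered out by thresholds")
            self.ranked_edges_ = RankedEdgeList(edges, directed=False, method_tag="rn", meta=meta)
        return self


# ---------------------------------------------------------------------------
# shrinkage GGM


def _shrunk_correlation(x: np.ndarray) -> tuple[np.ndarray, float]:
    """Correlation matrix shrunk toward the identity with the closed-form
    intensity  lambda* = sum Var(r_ij) / sum r_ij^2  (off-diagonal sums),
    clipped to [0, 1].  Var(r_ij) is the usual unbiased estimate from the
    per-sample products of standardized values."""
    n_genes, n = x.shape
    sd = x.std(axis=1, ddof=1)
    sd = np.where(sd == 0, 1.0, sd)
    xs = (x - x.mean(axis=1, keepdims=True)) / sd[:, None]
    r = (xs @ xs.T) / (n - 1)
    np.fill_diagonal(r, 1.0)
    # w_kij = xs_ik * xs_jk ; Var(r_ij) = n/(n-1)^3 * sum_k (w_kij - mean_k w_kij)^2
    wbar = (xs @ xs.T) / n
    w2 = (xs**2) @ (xs.T**2)  # sum_k w_kij^2
    var_r = n / (n - 1.0) ** 3 * (w2 - n * wbar**2)
    off = ~np.eye(n_genes, dtype=bool)
    denom = float((r[off] ** 2).sum())
    lam = 1.0 if denom == 0 else float(np.clip(var_r[off].sum() / denom, 0.0, 1.0))
    r_shrunk = (1.0 - lam) * r
    np.fill_diagonal(r_shrunk, 1.0)
    return r_shrunk, lam


def _pcor_from_inverse(omega: np.ndarray) -> np.ndarray:
    d = np.sqrt(np.diag(omega))
    p = -omega / np.outer(d, d)
    np.fill_diagonal(p, 1.0)
    return p


class GGMNetwork(BaseNetworkInference):
    """Graphical Gaussian model ranked by absolute shrinkage partial
    correlation.

    The sample correlation matrix is shrunk toward the identity with an
    analytic intensity (fitted attribute ``shrinkage_``) and inverted; the
    partial correlation of each pair conditions on all remaining genes.
    Ranking is by |pcor| only — the empirical-Bayes fdr machinery of the
    original shrinkage-GGM proposal induces the same ordering under its
    two-groups model, so it adds nothing to a rank-based pipeline.
    """

    def fit(self, X, y=None):
        expr = as_expression(X)
        if expr.n_genes < 2:
            raise ValueError("GGM needs at least 2 genes")
        self._set_fitted_meta(expr)
        r_shrunk, lam = _shrunk_correlation(expr.values)
        self.shrinkage_ = lam
        omega = np.linalg.inv(r_shrunk)
        pcor = _pcor_from_inverse(omega)
        self.partial_correlations_ = pcor
        self.ranked_edges_ = _all_pairs(expr.gene_ids, np.abs(pcor), pcor, tag="ggm")
        return self


# ---------------------------------------------------------------------------
# mutual information + CLR


def _bspline_weight_matrix(x: np.ndarray, bins: int, order: int) -> np.ndarray:
    """Per-sample B-spline membership weights over ``bins`` basis functions.

    Values are min-max scaled to [0, 1]; the clamped uniform knot vector
    gives a partition of unity, so each sample distributes one unit of mass
    over adjacent bins (generalized, smoothed histogram).  A constant gene
    puts all its mass in bin 0 for every sample.
    """
    lo, hi = x.min(), x.max()
    u = np.zeros_like(x, dtype=float) if hi == lo else (x - lo) / (hi - lo)
    degree = order - 1
    interior = np.linspace(0.0, 1.0, bins - order + 2)[1:-1]
    t = np.concatenate([np.zeros(order), interior, np.ones(order)])
    # keep the right endpoint inside the last knot span
    u = np.clip(u, 0.0, 1.0 - 1e-12)
    w = BSpline.design_matrix(u, t, degree).toarray()
    return w


def _entropy(p: np.ndarray) -> float:
    p = p[p > 0]
    return float(-(p * np.log(p)).sum())


def mutual_information_matrix(
    expr: ExpressionMatrix | np.ndarray,
    estimator: str = "bspline",
    bins: int = 10,
    spline_order: int = 3,
) -> np.ndarray:
    """Pairwise mutual information (nats) between all genes.

    estimator="bspline"
        Smoothed-histogram estimator: each sample contributes fractional
        counts to adjacent bins through B-spline basis functions, which
        reduces the discretization sensitivity of a hard histogram.
    estimator="gaussian"
        Closed form -0.5 ln(1 - r^2) under a bivariate normal assumption;
        fast, monotone in |r|.
    """
    expr = as_expression(expr)
    x = expr.values
    n_genes = expr.n_genes
    if estimator == "gaussian":
        r = pearson_matrix(expr)
        r2 = np.clip(r**2, 0.0, 1.0 - 1e-12)
        mi = -0.5 * np.log(1.0 - r2)
        np.fill_diagonal(mi, -0.5 * np.log(1e-12))  # self-MI: maximal per row
        return mi
    if estimator != "bspline":
        raise ValueError(f"unknown MI estimator {estimator!r}")
    if not (bins >= spline_order >= 1) or bins < 2:
        raise ValueError(f"need bins >= spline_order >= 1 and bins >= 2, got ({bins}, {spline_order})")
    weights = [_bspline_weight_matrix(x[g], bins, spline_order) for g in range(n_genes)]
    marg_h = np.empty(n_genes)
    for g in range(n_genes):
        marg_h[g] = _entropy(weights[g].mean(axis=0))
    n = x.shape[1]
    mi = np.zeros((n_genes, n_genes))
    for i in range(n_genes):
        wi = weights[i]
        for j in range(i, n_genes):
            joint = wi.T @ weights[j] / n
            h_ij = _entropy(joint.ravel())
            mi[i, j] = mi[j, i] = max(0.0, marg_h[i] + marg_h[j] - h_ij)
    return mi


def clr_scores(mi: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """CLR background correction of an MI matrix.

    z_i(j) = max(0, (MI_ij - mean_i) / sd_i), statistics taken over gene
    i's MI background (row i excluding the diagonal, population sd); the
    symmetric edge score is sqrt(z_i(j)^2 + z_j(i)^2).  Rows are treated
    independently, so the score is invariant to adding a constant to one
    gene's entire MI row.  A constant background (sd 0) yields z = 0 for
    that gene, logged.
    """
    mi = np.asarray(mi, dtype=float)
    n = mi.shape[0]
    off = ~np.eye(n, dtype=bool)
    z = np.zeros((n, n))
    for i in range(n):
        row = mi[i][off[i]]
        mu, sd = row.mean(), row.std()
        if sd == 0:
            logger.warning("CLR: gene %d has a constant MI background; z set to 0", i)
            continue
        z[i] = np.maximum(0.0, (mi[i] - mu) / sd)
    return np.sqrt(z**2 + z.T**2), z


class CLRNetwork(BaseNetworkInference):
    """Context likelihood of relatedness.

    The raw MI matrix is corrected against each gene's own MI background
    (see :func:`clr_scores`), which suppresses promiscuous genes whose MI
    is high with everything.
    """

    def __init__(self, estimator: str = "bspline", bins: int = 10, spline_order: int = 3):
        self.estimator = estimator
        self.bins = bins
        self.spline_order = spline_order

    def fit(self, X, y=None):
        expr = as_expression(X)
        self._set_fitted_meta(expr)
        mi = mutual_information_matrix(
            expr, estimator=self.estimator, bins=self.bins, spline_order=self.spline_order
        )
        self.mi_matrix_ = mi
        score, z = clr_scores(mi)
        self.zscores_ = z
        self.ranked_edges_ = _all_pairs(expr.gene_ids, score, tag="clr")
        return self


# ---------------------------------------------------------------------------
# thin function wrappers


def relevance_network(
    expr, pos_threshold: float = 0.9, neg_threshold: float = -1.0, emit_all: bool = False
) -> RankedEdgeList:
    return RelevanceNetwork(pos_threshold, neg_threshold, emit_all).fit_network(expr)


def ggm_network(expr) -> RankedEdgeList:
    return GGMNetwork().fit_network(expr)


def clr_network(expr, estimator: str = "bspline", bins: int = 10, spline_order: int = 3) -> RankedEdgeList:
    return CLRNetwork(estimator, bins, spline_order).fit_network(expr)
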