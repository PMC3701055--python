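"""Estimator plumbing shared by all network-inference estimators.

Every inference algorithm in this package is a scikit-learn style estimator:
hyperparameters in ``__init__``, a ``fit(X)`` that accepts either an
:class:`~grninfer.datatypes.ExpressionMatrix`, a pandas DataFrame
(samples x genes, sklearn orientation) or a bare 2-D array, and fitted
attributes with a trailing underscore — chiefly ``ranked_edges_``, the
scored edge list every downstream operation consumes.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator

from .datatypes import ExpressionMatrix, RankedEdgeList


def as_expression(X) -> ExpressionMatrix:
    """Coerce estimator input into a genes x samples ExpressionMatrix.

    DataFrames and arrays follow the sklearn convention of samples in rows
    and features (genes) in columns; ExpressionMatrix instances pass
    through unchanged.  Bare arrays get synthetic gene ids g0, g1, ...
    """
    if isinstance(X, ExpressionMatrix):
        return X
    if isinstance(X, pd.DataFrame):
        return ExpressionMatrix.from_frame(X, orientation="genes_in_columns")
    arr = np.asarray(X, dtype=float)
    if arr.ndim != 2:
        raise ValueError(f"expected a 2-D array, got shape {arr.shape}")
    n_samples, n_genes = arr.shape
    width = max(1, len(str(n_genes - 1)))
    genes = [f"g{i:0{width}d}" for i in range(n_genes)]
    samples = [f"s{j}" for j in range(n_samples)]
    return ExpressionMatrix(genes, samples, arr.T)


class BaseNetworkInference(BaseEstimator):
    """Base class: fit an expression matrix, expose a ranked edge list."""

    #: set by fit()
    ranked_edges_: RankedEdgeList

    def fit(self, X, y=None):  # pragma: no cover - abstract
        raise NotImplementedError

    def fit_network(self, X) -> RankedEdgeList:
        """Convenience: fit and return the ranked edge list."""
        return self.fit(X).ranked_edges_

    def _set_fitted_meta(self, expr: ExpressionMatrix) -> None:
        self.gene_ids_ = list(expr.gene_ids)
        self.n_features_in_ = expr.n_genes
        self.feature_names_in_ = np.asarray(expr.gene_ids, dtype=object)
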