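"""Core in-memory data model shared by every inference and analysis module.

The two workhorse containers are :class:`ExpressionMatrix` (genes x samples,
the input to every inference algorithm) and :class:`RankedEdgeList` (scored
regulator-target pairs with a deterministic total order, the universal
currency between algorithms, Borda integration and evaluation).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Iterator, Mapping, Sequence

import numpy as np
import pandas as pd

from ._utils import logger

__all__ = [
    "ExpressionMatrix",
    "RankedEdgeList",
    "GoldStandard",
    "AnnotationTable",
    "match_tf_list",
]


@dataclass
class ExpressionMatrix:
    """A genes x samples matrix of (normalized, unitless) expression values.

    Invariants enforced at construction: unique gene and sample identifiers,
    a finite numeric body, and at least 3 samples (no pairwise statistic in
    the toolkit is defined below that).
    """

    gene_ids: list[str]
    sample_ids: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.gene_ids = [str(g) for g in self.gene_ids]
        self.sample_ids = [str(s) for s in self.sample_ids]
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.gene_ids), len(self.sample_ids)):
            raise ValueError(
                f"values shape {self.values.shape} does not match "
                f"{len(self.gene_ids)} genes x {len(self.sample_ids)} samples"
            )
        dupes = _duplicates(self.gene_ids)
        if dupes:
            raise ValueError(f"duplicate gene identifiers: {sorted(dupes)}")
        if _duplicates(self.sample_ids):
            raise ValueError("duplicate sample identifiers")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("expression matrix contains non-finite values")
        if self.n_samples < 3:
            raise ValueError(f"need at least 3 samples, got {self.n_samples}")

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @classmethod
    def from_frame(cls, df: pd.DataFrame, orientation: str = "genes_in_rows") -> "ExpressionMatrix":
        if orientation == "genes_in_columns":
            df = df.T
        elif orientation != "genes_in_rows":
            raise ValueError(f"unknown orientation {orientation!r}")
        return cls(list(df.index.astype(str)), list(df.columns.astype(str)), df.to_numpy(dtype=float))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.gene_ids, columns=self.sample_ids)

    def subset_genes(self, genes: Sequence[str]) -> "ExpressionMatrix":
        index = {g: i for i, g in enumerate(self.gene_ids)}
        missing = [g for g in genes if g not in index]
        if missing:
            raise KeyError(f"genes not in matrix: {missing[:5]}")
        rows = [index[g] for g in genes]
        return ExpressionMatrix(list(genes), list(self.sample_ids), self.values[rows])


def match_tf_list(tf_ids: Iterable[str], expr: ExpressionMatrix) -> list[str]:
    """Intersect a transcription-factor list with the genes of a matrix.

    IDs absent from the matrix are dropped with a logged count (exact,
    case-sensitive string matching).  An empty intersection is an error:
    regression-based methods have no candidate regulators without it.
    """
    present = set(expr.gene_ids)
    tf_ids = [str(t) for t in tf_ids]
    kept = [t for t in dict.fromkeys(tf_ids) if t in present]
    n_dropped = len(set(tf_ids)) - len(kept)
    if n_dropped:
        logger.warning("dropped %d TF ids not present in the expression matrix", n_dropped)
    if not kept:
        raise ValueError("no TF id matches any gene in the expression matrix")
    # preserve matrix order for determinism
    order = {g: i for i, g in enumerate(expr.gene_ids)}
    return sorted(kept, key=order.__getitem__)


class RankedEdgeList:
    """Scored (regulator, target, score) triples with a deterministic order.

    Edges are sorted by descending score, ties broken lexicographically on
    (regulator, target) so that the integer ranks handed to Borda-count
    integration are reproducible.  Undirected lists store each unordered
    pair once, in canonical orientation (lexicographically smaller id
    first).  Self-edges and duplicate pairs are rejected.

    ``meta`` carries optional per-edge annotations (correlation sign,
    PLPC orientation, supporting methods ...) keyed after sorting.
    """

    def __init__(
        self,
        edges: Iterable[tuple[str, str, float]],
        directed: bool,
        method_tag: str = "",
        meta: Sequence[Mapping] | None = None,
    ) -> None:
        rows = []
        meta = list(meta) if meta is not None else None
        for k, (a, b, s) in enumerate(edges):
            a, b, s = str(a), str(b), float(s)
            if a == b:
                raise ValueError(f"self-edge {a!r} not allowed")
            m = dict(meta[k]) if meta is not None else {}
            if not directed and a > b:
                a, b = b, a
            rows.append((a, b, s, m))
        rows.sort(key=lambda r: (-r[2], r[0], r[1]))
        pairs = [(a, b) for a, b, _, _ in rows]
        if len(set(pairs)) != len(pairs):
            dupe = _duplicates(pairs)
            raise ValueError(f"duplicate edge pairs: {sorted(dupe)[:5]}")
        self.regulators: list[str] = [r[0] for r in rows]
        self.targets: list[str] = [r[1] for r in rows]
        self.scores: np.ndarray = np.array([r[2] for r in rows], dtype=float)
        self.meta: list[dict] = [r[3] for r in rows]
        self.directed = bool(directed)
        self.method_tag = str(method_tag)

    def __len__(self) -> int:
        return len(self.regulators)

    def __iter__(self) -> Iterator[tuple[str, str, float]]:
        return iter(zip(self.regulators, self.targets, self.scores))

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, RankedEdgeList):
            return NotImplemented
        return (
            self.directed == other.directed
            and self.regulators == other.regulators
            and self.targets == other.targets
            and np.allclose(self.scores, other.scores, rtol=0, atol=1e-9)
        )

    def top(self, k: int | None) -> "RankedEdgeList":
        """First ``k`` edges of the ranking (all edges if ``k`` is None)."""
        if k is None or k >= len(self):
            return self
        return RankedEdgeList(
            list(zip(self.regulators[:k], self.targets[:k], self.scores[:k])),
            directed=self.directed,
            method_tag=self.method_tag,
            meta=self.meta[:k],
        )

    def ranks(self) -> dict[tuple[str, str], int]:
        """1-based rank of every edge keyed by (regulator, target)."""
        return {pair: i + 1 for i, pair in enumerate(zip(self.regulators, self.targets))}

    def nodes(self) -> set[str]:
        return set(self.regulators) | set(self.targets)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"regulator": self.regulators, "target": self.targets, "score": self.scores}
        )


@dataclass
class GoldStandard:
    """Known interaction labels: (regulator, target) -> 0/1.

    The labeled pairs define the evaluable universe used by the DREAM-style
    AUC evaluation; unlabeled pairs are ignored, not treated as negatives.
    """

    labels: dict[tuple[str, str], int]
    directed: bool = True

    def __post_init__(self) -> None:
        clean: dict[tuple[str, str], int] = {}
        for (a, b), v in self.labels.items():
            a, b = str(a), str(b)
            if a == b:
                raise ValueError(f"self-edge {a!r} in gold standard")
            if v not in (0, 1):
                raise ValueError(f"gold-standard label must be 0/1, got {v!r}")
            if not self.directed and a > b:
                a, b = b, a
            if (a, b) in clean and clean[(a, b)] != v:
                raise ValueError(f"conflicting labels for pair {(a, b)}")
            clean[(a, b)] = v
        self.labels = clean

    @property
    def positives(self) -> set[tuple[str, str]]:
        return {p for p, v in self.labels.items() if v == 1}

    @property
    def negatives(self) -> set[tuple[str, str]]:
        return {p for p, v in self.labels.items() if v == 0}

    def __len__(self) -> int:
        return len(self.labels)


@dataclass
class AnnotationTable:
    """gene_id -> set of annotation term ids (GO / pathway), plus optional
    free-text descriptions."""

    terms: dict[str, set[str]] = field(default_factory=dict)
    descriptions: dict[str, str] = field(default_factory=dict)

    def genes_for_term(self, term: str) -> set[str]:
        return {g for g, ts in self.terms.items() if term in ts}

    def all_terms(self) -> set[str]:
        out: set[str] = set()
        for ts in self.terms.values():
            out |= ts
        return out


def _duplicates(items: Iterable) -> set:
    seen, dup = set(), set()
    for x in items:
        if x in seen:
            dup.add(x)
        seen.add(x)
    return dup
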