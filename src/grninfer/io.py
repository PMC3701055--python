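"""Readers and writers for every external text format the toolkit touches.

All formats are plain tab-delimited text: expression matrices, one-id-per-line
TF lists, 3-column edge lists, 3-column gold standards, 12-column tabular
protein-similarity output ("outfmt 6"), 2-column gene-to-term annotation
tables, and partially-directed networks (edge TSV with an orientation mark).

Readers reject malformed input with errors that name the offending row or
column; writer/reader pairs are exact inverses on valid data (scores to at
least 1e-9, printed with 10 significant digits).
"""

from __future__ import annotations

import os
from typing import Iterable

import numpy as np
import pandas as pd

from ._utils import logger
from .datatypes import AnnotationTable, ExpressionMatrix, GoldStandard, RankedEdgeList

BLAST_COLUMNS = [
    "query_id",
    "subject_id",
    "pct_identity",
    "aln_len",
    "mismatches",
    "gap_opens",
    "q_start",
    "q_end",
    "s_start",
    "s_end",
    "evalue",
    "bit_score",
]

ORIENT_MARKS = {"--": None, "->": "forward", "<-": "backward"}


def read_expression(
    path: str | os.PathLike,
    orientation: str = "genes_in_rows",
    drop_missing: bool = True,
) -> ExpressionMatrix:
    """Read a tab-delimited expression matrix.

    The first row holds sample ids and the first column gene ids (or the
    transpose, with ``orientation="genes_in_columns"``).  Genes with any
    missing/non-numeric cell are dropped with a logged count when
    ``drop_missing`` is true, otherwise the offending cell is reported as a
    parse error.  Values are never imputed.
    """
    df = pd.read_csv(path, sep="\t", index_col=0, na_values=["NA", "NaN", "nan", ""])
    if orientation == "genes_in_columns":
        df = df.T
    elif orientation != "genes_in_rows":
        raise ValueError(f"unknown orientation {orientation!r}")
    df.index = df.index.astype(str)
    df.columns = df.columns.astype(str)
    numeric = df.apply(pd.to_numeric, errors="coerce")
    bad = numeric.isna()
    if bad.to_numpy().any():
        if not drop_missing:
            r = bad.any(axis=1).idxmax()
            c = bad.loc[r].idxmax()
            raise ValueError(f"non-numeric or missing value at gene {r!r}, sample {c!r}")
        bad_genes = bad.any(axis=1)
        logger.warning("dropped %d gene(s) with missing/non-numeric values", int(bad_genes.sum()))
        numeric = numeric.loc[~bad_genes]
    dupes = numeric.index[numeric.index.duplicated()].unique().tolist()
    if dupes:
        raise ValueError(f"duplicate gene identifiers: {dupes[:10]}")
    return ExpressionMatrix.from_frame(numeric)


def write_expression(expr: ExpressionMatrix, path: str | os.PathLike) -> None:
    expr.to_frame().to_csv(path, sep="\t", float_format="%.10g")


def read_tf_list(path: str | os.PathLike) -> list[str]:
    """Read a one-id-per-line transcription-factor list (blank lines skipped)."""
    with open(path) as fh:
        ids = [line.strip() for line in fh if line.strip()]
    return list(dict.fromkeys(ids))


def write_tf_list(tf_ids: Iterable[str], path: str | os.PathLike) -> None:
    with open(path, "w") as fh:
        for t in tf_ids:
            fh.write(f"{t}\n")


def write_edges(edges: RankedEdgeList, path: str | os.PathLike, header: bool = True) -> None:
    """Write a ranked edge list as 3-column TSV (regulator, target, score).

    Scores are printed with 10 significant digits so a round-trip preserves
    the ranking and the values to well below 1e-9.  A PLPC orientation mark
    stored in edge metadata is emitted as a 4th column in {--, ->, <-}.
    """
    has_orient = any("orientation" in m for m in edges.meta)
    with open(path, "w") as fh:
        if header:
            cols = ["regulator", "target", "score"] + (["direction"] if has_orient else [])
            fh.write("\t".join(cols) + "\n")
        for i, (a, b, s) in enumerate(edges):
            row = f"{a}\t{b}\t{s:.10g}"
            if has_orient:
                mark = {"forward": "->", "backward": "<-", None: "--"}[
                    edges.meta[i].get("orientation")
                ]
                row += f"\t{mark}"
            fh.write(row + "\n")


def read_edges(
    path: str | os.PathLike, directed: bool = True, method_tag: str = ""
) -> RankedEdgeList:
    rows, meta = [], []
    with open(path) as fh:
        for ln, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if parts[0] == "regulator":  # header
                continue
            if len(parts) < 3:
                raise ValueError(f"{path}: line {ln}: expected >=3 tab-separated columns")
            try:
                score = float(parts[2])
            except ValueError as exc:
                raise ValueError(f"{path}: line {ln}: non-numeric score {parts[2]!r}") from exc
            rows.append((parts[0], parts[1], score))
            m = {}
            if len(parts) >= 4 and parts[3] in ORIENT_MARKS:
                m["orientation"] = ORIENT_MARKS[parts[3]]
            meta.append(m)
    return RankedEdgeList(rows, directed=directed, method_tag=method_tag, meta=meta)


def read_gold_standard(path: str | os.PathLike, directed: bool = True) -> GoldStandard:
    """Read a 3-column (regulator, target, 0/1) gold standard."""
    labels: dict[tuple[str, str], int] = {}
    with open(path) as fh:
        for ln, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if parts[0] == "regulator":
                continue
            if len(parts) < 3:
                raise ValueError(f"{path}: line {ln}: expected 3 tab-separated columns")
            try:
                label = int(parts[2])
            except ValueError as exc:
                raise ValueError(f"{path}: line {ln}: label must be 0 or 1") from exc
            if label not in (0, 1):
                raise ValueError(f"{path}: line {ln}: label must be 0 or 1, got {label}")
            a, b = parts[0], parts[1]
            key = (a, b) if directed or a <= b else (b, a)
            if key in labels and labels[key] != label:
                raise ValueError(f"{path}: line {ln}: conflicting labels for pair {key}")
            labels[key] = label
    return GoldStandard(labels, directed=directed)


def write_gold_standard(gold: GoldStandard, path: str | os.PathLike) -> None:
    with open(path, "w") as fh:
        for (a, b), v in sorted(gold.labels.items()):
            fh.write(f"{a}\t{b}\t{v}\n")


def read_blast_table(path: str | os.PathLike) -> pd.DataFrame:
    """Read 12-column tabular protein-similarity output (BLAST outfmt 6)."""
    try:
        df = pd.read_csv(path, sep="\t", header=None, names=BLAST_COLUMNS, comment="#")
    except Exception as exc:
        raise ValueError(f"{path}: cannot parse as 12-column tabular output: {exc}") from exc
    if df.shape[1] != 12:
        raise ValueError(f"{path}: expected 12 columns, got {df.shape[1]}")
    for col in ("evalue", "bit_score"):
        df[col] = pd.to_numeric(df[col], errors="raise")
    if (df["evalue"] < 0).any():
        raise ValueError(f"{path}: negative E-value")
    if not np.all(np.isfinite(df["bit_score"])):
        raise ValueError(f"{path}: non-finite bit score")
    df["query_id"] = df["query_id"].astype(str)
    df["subject_id"] = df["subject_id"].astype(str)
    return df


def read_annotation(path: str | os.PathLike) -> AnnotationTable:
    """Read a 2(+1)-column gene <tab> term [<tab> description] table."""
    table = AnnotationTable()
    with open(path) as fh:
        for ln, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) < 2:
                raise ValueError(f"{path}: line {ln}: expected gene<TAB>term")
            gene, term = parts[0], parts[1]
            table.terms.setdefault(gene, set()).add(term)
            if len(parts) >= 3 and parts[2]:
                table.descriptions[gene] = parts[2]
    return table


def read_alias_map(path: str | os.PathLike) -> dict[str, str]:
    """Optional 2-column alias map (e.g. probeset id <-> gene id)."""
    out: dict[str, str] = {}
    with open(path) as fh:
        for ln, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) != 2:
                raise ValueError(f"{path}: line {ln}: expected exactly 2 columns")
            out[parts[0]] = parts[1]
    return out
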