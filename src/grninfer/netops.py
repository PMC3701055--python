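"""Network utilities: subnetwork query, cross-species comparison via
reciprocal-best-hit metagenes, and chi-square annotation-term enrichment.

Cross-species comparison works by translating each species' network onto a
shared node vocabulary of *metagenes* — ortholog clusters derived from
all-against-all protein-similarity searches by the reciprocal-best-hit
(RBH) criterion: two genes in two genomes are orthologs when each is the
other's best hit.  A duplicated genome (soybean-style) may contribute its
best two hits instead of one.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from ._utils import logger
from .datatypes import AnnotationTable, RankedEdgeList

__all__ = [
    "MetageneTable",
    "CompositeNetwork",
    "subnetwork",
    "best_hits",
    "rbh_orthologs",
    "build_metagenes",
    "compare_networks",
    "go_enrichment",
]


# ---------------------------------------------------------------------------
# subnetwork query


def subnetwork(
    net: RankedEdgeList,
    seeds: list[str],
    mode: str = "neighbors_of_seeds",
    top_edges: int | None = None,
    tf_ids: set[str] | None = None,
) -> RankedEdgeList:
    """Immediate connections of a seed gene list, optionally truncated.

    mode="neighbors_of_seeds" keeps edges with at least one endpoint in the
    seed list; mode="tf_first_connections" keeps edges whose TF endpoint is
    a seed (requires ``tf_ids``).  The surviving edges are then truncated to
    the ``top_edges`` most confident ones.
    """
    seeds_set = {str(s) for s in seeds}
    if not seeds_set & net.nodes():
        logger.warning("subnetwork: no seed gene appears in the network")
    if mode == "neighbors_of_seeds":
        keep = [
            k for k, (a, b, _) in enumerate(net) if a in seeds_set or b in seeds_set
        ]
    elif mode == "tf_first_connections":
        if tf_ids is None:
            raise ValueError("tf_first_connections mode needs tf_ids")
        tf_ids = {str(t) for t in tf_ids}
        keep = [
            k
            for k, (a, b, _) in enumerate(net)
            if (a in tf_ids and a in seeds_set) or (b in tf_ids and b in seeds_set)
        ]
    else:
        raise ValueError(f"unknown subnetwork mode {mode!r}")
    sub = RankedEdgeList(
        [(net.regulators[k], net.targets[k], net.scores[k]) for k in keep],
        directed=net.directed,
        method_tag=net.method_tag,
        meta=[net.meta[k] for k in keep],
    )
    return sub.top(top_edges)


# ---------------------------------------------------------------------------
# reciprocal best hits


def best_hits(table: pd.DataFrame, evalue_threshold: float = 1e-6, max_hits: int = 1) -> dict[str, set[str]]:
    """Best subject(s) per query from a 12-column similarity table.

    Hits above the E-value threshold are discarded; the remainder are
    sorted by descending bit score, then ascending E-value, then subject id
    (a deterministic tie-break).  The top ``max_hits`` distinct subjects are
    kept per query, extended by any further subject exactly tied with the
    last kept one on (bit score, E-value) — exact ties are treated as
    multiple co-orthologs.
    """
    kept = table[table["evalue"] <= evalue_threshold]
    out: dict[str, set[str]] = {}
    for query, grp in kept.groupby("query_id", sort=False):
        grp = grp.sort_values(
            ["bit_score", "evalue", "subject_id"], ascending=[False, True, True]
        )
        subjects: set[str] = set()
        last_key = None
        for row in grp.itertuples(index=False):
            key = (row.bit_score, row.evalue)
            if len(subjects) < max_hits or key == last_key:
                subjects.add(row.subject_id)
                last_key = key
            else:
                break
        if subjects:
            out[str(query)] = subjects
    return out


def rbh_orthologs(
    ab: pd.DataFrame,
    ba: pd.DataFrame,
    evalue_threshold: float = 1e-6,
    max_hits_a: int = 1,
    max_hits_b: int = 1,
) -> set[tuple[str, str]]:
    """Reciprocal-best-hit ortholog pairs between genomes A and B.

    ``ab`` holds hits of A proteins against genome B, ``ba`` the reverse.
    A pair (a, b) is emitted iff b is among a's best hit(s) and a among
    b's.  ``max_hits_a`` / ``max_hits_b`` allow a duplicated genome to
    contribute its best two hits (set the corresponding side to 2).
    """
    best_ab = best_hits(ab, evalue_threshold, max_hits_b)
    best_ba = best_hits(ba, evalue_threshold, max_hits_a)
    pairs = set()
    for a, subjects in best_ab.items():
        for b in subjects:
            if a in best_ba.get(b, set()):
                pairs.add((a, b))
    return pairs


# ---------------------------------------------------------------------------
# metagenes


@dataclass
class MetageneTable:
    """Cross-species ortholog clusters keyed by metagene id.

    ``members`` maps metagene_id -> set of (species, gene_id); ``flagged``
    lists metagenes whose composition exceeds the per-species member
    allowance (surfaced, not silently resolved).
    """

    members: dict[str, set[tuple[str, str]]] = field(default_factory=dict)
    flagged: set[str] = field(default_factory=set)

    def gene_to_metagene(self, species: str) -> dict[str, str]:
        out = {}
        for mg, mem in self.members.items():
            for sp, g in mem:
                if sp == species:
                    out[g] = mg
        return out

    def to_frame(self) -> pd.DataFrame:
        rows = [
            (mg, sp, g, mg in self.flagged)
            for mg, mem in sorted(self.members.items())
            for sp, g in sorted(mem)
        ]
        return pd.DataFrame(rows, columns=["metagene_id", "species", "gene_id", "flagged"])


def build_metagenes(
    pairsets: dict[tuple[str, str], set[tuple[str, str]]],
    max_members: dict[str, int] | None = None,
) -> MetageneTable:
    """Merge pairwise ortholog sets into metagene clusters.

    ``pairsets`` maps a species pair (A, B) to RBH pairs (gene_in_A,
    gene_in_B).  Metagenes are the connected components of the union
    ortholog graph that span at least two species.  Components holding more
    members of one species than that species' allowance (default 1; set 2
    for a duplicated genome) are kept but flagged.  Metagene ids are
    assigned deterministically by sorting components on their member sets.
    """
    max_members = max_members or {}
    g = nx.Graph()
    for (sp_a, sp_b), pairs in sorted(pairsets.items()):
        for a, b in sorted(pairs):
            g.add_edge((sp_a, str(a)), (sp_b, str(b)))
    components = [tuple(sorted(c)) for c in nx.connected_components(g)]
    components = [c for c in components if len({sp for sp, _ in c}) >= 2]
    components.sort()
    width = max(1, len(str(len(components))))
    table = MetageneTable()
    for k, comp in enumerate(components, start=1):
        mg = f"MG{k:0{width}d}"
        table.members[mg] = set(comp)
        counts: dict[str, int] = {}
        for sp, _ in comp:
            counts[sp] = counts.get(sp, 0) + 1
        if any(cnt > max_members.get(sp, 1) for sp, cnt in counts.items()):
            table.flagged.add(mg)
    return table


# ---------------------------------------------------------------------------
# composite networks


@dataclass
class CompositeNetwork:
    """Edge union of several networks with per-source presence and scores.

    ``edges`` maps an edge key (node pair, canonical order for undirected
    sources) to {source_name: score}.  Nodes are gene ids, or metagene ids
    when an id map was applied.
    """

    edges: dict[tuple[str, str], dict[str, float]] = field(default_factory=dict)
    sources: list[str] = field(default_factory=list)
    n_untranslated: dict[str, int] = field(default_factory=dict)

    def edges_in_all(self) -> list[tuple[str, str]]:
        return sorted(e for e, srcs in self.edges.items() if len(srcs) == len(self.sources))

    def edges_unique_to(self, source: str) -> list[tuple[str, str]]:
        return sorted(e for e, srcs in self.edges.items() if set(srcs) == {source})

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for (a, b), srcs in sorted(self.edges.items()):
            row = {"node_a": a, "node_b": b}
            for s in self.sources:
                row[s] = srcs.get(s, np.nan)
            rows.append(row)
        return pd.DataFrame(rows, columns=["node_a", "node_b", *self.sources])


def compare_networks(
    nets: dict[str, RankedEdgeList],
    id_map: MetageneTable | None = None,
    species_of: dict[str, str] | None = None,
) -> CompositeNetwork:
    """Overlay >= 2 networks into a composite with per-source edge labels.

    With an ``id_map``, each network's nodes are first translated to
    metagene ids using ``species_of[source]``; edges with an untranslatable
    endpoint are dropped and counted.  Edges are keyed by canonical
    unordered pair so networks from undirected and directed methods
    overlay consistently; a pair predicted in both orientations keeps its
    best score per source.
    """
    if len(nets) < 2:
        raise ValueError("network comparison needs >= 2 networks")
    comp = CompositeNetwork(sources=sorted(nets))
    for name in comp.sources:
        net = nets[name]
        translate = None
        if id_map is not None:
            if species_of is None or name not in species_of:
                raise ValueError(f"species_of must name the species of network {name!r}")
            translate = id_map.gene_to_metagene(species_of[name])
        dropped = 0
        for a, b, s in net:
            if translate is not None:
                if a not in translate or b not in translate:
                    dropped += 1
                    continue
                a, b = translate[a], translate[b]
                if a == b:  # both endpoints collapse onto one metagene
                    dropped += 1
                    continue
            key = (a, b) if a <= b else (b, a)
            scores = comp.edges.setdefault(key, {})
            if name not in scores or s > scores[name]:
                scores[name] = float(s)
        comp.n_untranslated[name] = dropped
        if dropped:
            logger.info("compare_networks: dropped %d untranslatable edge(s) from %s", dropped, name)
    return comp


# ---------------------------------------------------------------------------
# enrichment


def go_enrichment(
    subnet_genes: set[str],
    universe: set[str],
    annot: AnnotationTable,
    adjust: bool = True,
) -> pd.DataFrame:
    """Per-term chi-square enrichment of a gene set against a universe.

    For every annotation term a 2x2 table (in subnetwork vs not, has term
    vs not) over the universe is tested with the 1-df Pearson chi-square
    statistic, no continuity correction; the p-value is the upper tail.
    Terms whose table has a zero marginal (expected count 0) are skipped
    and logged.  A Benjamini-Hochberg adjusted column is added (the raw
    p-value is always reported); ``direction`` marks enrichment vs
    depletion of the term inside the subnetwork.
    """
    subnet_genes = {str(g) for g in subnet_genes}
    universe = {str(g) for g in universe}
    if not subnet_genes <= universe:
        raise ValueError("subnetwork genes must be a subset of the universe")
    n_univ = len(universe)
    n_sub = len(subnet_genes)
    rows = []
    for term in sorted(annot.all_terms()):
        has = annot.genes_for_term(term) & universe
        a = len(has & subnet_genes)  # in subnet, has term
        b = n_sub - a  # in subnet, lacks term
        c = len(has) - a  # outside, has term
        d = n_univ - n_sub - c  # outside, lacks term
        if min(a + b, c + d, a + c, b + d) == 0:
            logger.info("go_enrichment: term %s skipped (zero marginal)", term)
            continue
        chi2 = n_univ * (a * d - b * c) ** 2 / ((a + b) * (c + d) * (a + c) * (b + d))
        p = float(stats.chi2.sf(chi2, df=1))
        expected_a = (a + b) * (a + c) / n_univ
        rows.append(
            {
                "term": term,
                "in_subnet_with_term": a,
                "in_subnet_without_term": b,
                "out_subnet_with_term": c,
                "out_subnet_without_term": d,
                "chi2": float(chi2),
                "pvalue": p,
                "direction": "enriched" if a > expected_a else "depleted",
            }
        )
    df = pd.DataFrame(
        rows,
        columns=[
            "term",
            "in_subnet_with_term",
            "in_subnet_without_term",
            "out_subnet_with_term",
            "out_subnet_without_term",
            "chi2",
            "pvalue",
            "direction",
        ],
    )
    if adjust and len(df):
        df["pvalue_bh"] = multipletests(df["pvalue"], method="fdr_bh")[1]
    elif adjust:
        df["pvalue_bh"] = pd.Series(dtype=float)
    return df
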