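import numpy as np
import pandas as pd
import pytest
from scipy import stats

from grninfer import (
    AnnotationTable,
    RankedEdgeList,
    build_metagenes,
    compare_networks,
    go_enrichment,
    rbh_orthologs,
    subnetwork,
)
from grninfer.io import BLAST_COLUMNS


def blast_frame(rows):
    """rows: (query, subject, evalue, bit_score)"""
    data = [
        (q, s, 90.0, 100, 1, 0, 1, 100, 1, 100, ev, bs) for q, s, ev, bs in rows
    ]
    return pd.DataFrame(data, columns=BLAST_COLUMNS)


class TestSubnetwork:
    def net(self):
        return RankedEdgeList(
            [("a", "b", 0.9), ("b", "c", 0.8), ("c", "d", 0.7), ("d", "e", 0.6)],
            directed=False,
        )

    def test_isolated_seed_gives_empty(self):
        assert len(subnetwork(self.net(), ["zz"])) == 0

    def test_star_center_returns_all(self):
        star = RankedEdgeList([("hub", f"g{i}", 1.0 - i / 10) for i in range(5)], directed=False)
        assert len(subnetwork(star, ["hub"])) == 5

    def test_identity_on_full_seed_set(self):
        net = self.net()
        assert subnetwork(net, sorted(net.nodes())) == net

    def test_matches_brute_force_filter_then_truncate(self, rng):
        ids = [f"g{i}" for i in range(12)]
        pairs = list({(ids[i], ids[j]) for i, j in rng.integers(0, 12, (40, 2)) if i < j})[:20]
        net = RankedEdgeList(
            [(a, b, s) for (a, b), s in zip(pairs, rng.random(len(pairs)))], directed=False
        )
        seeds = ["g3", "g7"]
        expected = [(a, b, s) for a, b, s in net if a in seeds or b in seeds][:5]
        got = subnetwork(net, seeds, top_edges=5)
        assert [(a, b, round(s, 12)) for a, b, s in got] == [
            (a, b, round(s, 12)) for a, b, s in expected
        ]

    def test_tf_first_connections_mode(self):
        net = self.net()
        sub = subnetwork(net, ["b", "d"], mode="tf_first_connections", tf_ids={"b"})
        assert {frozenset(e[:2]) for e in sub} == {frozenset(("a", "b")), frozenset(("b", "c"))}


class TestRBH:
    def test_mutual_best_definition(self):
        ab = blast_frame([("a1", "b1", 1e-50, 200), ("a2", "b1", 1e-40, 150)])
        ba = blast_frame([("b1", "a1", 1e-50, 200)])
        pairs = rbh_orthologs(ab, ba)
        assert pairs == {("a1", "b1")}  # a2's best is b1, but b1 prefers a1

    def test_exact_ties_are_co_orthologs(self):
        ab = blast_frame([("a1", "b1", 1e-50, 200), ("a1", "b2", 1e-50, 200)])
        ba = blast_frame([("b1", "a1", 1e-50, 200), ("b2", "a1", 1e-45, 180)])
        pairs = rbh_orthologs(ab, ba)
        assert pairs == {("a1", "b1"), ("a1", "b2")}

    def test_two_best_hits_rule_for_duplicated_genome(self):
        # duplicated genome B: keep a1's best two hits, both reciprocate
        ab = blast_frame([("a1", "b1", 1e-60, 220), ("a1", "b2", 1e-50, 180)])
        ba = blast_frame([("b1", "a1", 1e-60, 220), ("b2", "a1", 1e-50, 180)])
        assert rbh_orthologs(ab, ba, max_hits_b=2) == {("a1", "b1"), ("a1", "b2")}
        assert rbh_orthologs(ab, ba) == {("a1", "b1")}

    def test_evalue_threshold_filters(self):
        ab = blast_frame([("a1", "b1", 1e-3, 200)])
        ba = blast_frame([("b1", "a1", 1e-3, 200)])
        assert rbh_orthologs(ab, ba) == set()
        assert rbh_orthologs(ab, ba, evalue_threshold=1e-2) == {("a1", "b1")}

    def test_symmetry(self):
        ab = blast_frame([("a1", "b1", 1e-50, 200), ("a2", "b2", 1e-30, 120)])
        ba = blast_frame([("b1", "a1", 1e-50, 200), ("b2", "a2", 1e-30, 120)])
        fwd = rbh_orthologs(ab, ba)
        rev = rbh_orthologs(ba, ab)
        assert {(b, a) for a, b in fwd} == rev


class TestMetagenes:
    def test_single_pair(self):
        table = build_metagenes({("M", "L"): {("m1", "l1")}})
        assert len(table.members) == 1
        (members,) = table.members.values()
        assert members == {("M", "m1"), ("L", "l1")}
        assert not table.flagged

    def test_triangle_merges_to_one(self):
        table = build_metagenes(
            {
                ("M", "L"): {("m1", "l1")},
                ("M", "G"): {("m1", "g1")},
                ("L", "G"): {("l1", "g1")},
            }
        )
        assert len(table.members) == 1
        (members,) = table.members.values()
        assert len(members) == 3

    def test_chain_with_duplicate_species_flagged(self):
        table = build_metagenes(
            {
                ("M", "L"): {("m1", "l1")},
                ("L", "G"): {("l1", "g1")},
                ("G", "M"): {("g1", "m2")},
            }
        )
        assert len(table.members) == 1
        mg = next(iter(table.members))
        assert len(table.members[mg]) == 4
        assert mg in table.flagged  # two M members exceed the allowance of 1
        # with an allowance of 2 for M the same component is unflagged
        table2 = build_metagenes(
            {
                ("M", "L"): {("m1", "l1")},
                ("L", "G"): {("l1", "g1")},
                ("G", "M"): {("g1", "m2")},
            },
            max_members={"M": 2},
        )
        assert not table2.flagged

    def test_input_order_invariance_and_stable_ids(self):
        sets_a = {("M", "L"): {("m1", "l1"), ("m2", "l2")}, ("L", "G"): {("l2", "g2")}}
        sets_b = {("L", "G"): {("l2", "g2")}, ("M", "L"): {("m2", "l2"), ("m1", "l1")}}
        ta, tb = build_metagenes(sets_a), build_metagenes(sets_b)
        assert ta.members == tb.members
        assert list(ta.members) == sorted(ta.members)


class TestCompareNetworks:
    def test_identical_networks_fully_shared(self):
        net = RankedEdgeList([("a", "b", 0.9), ("b", "c", 0.8)], directed=False)
        comp = compare_networks({"x": net, "y": net})
        assert comp.edges_in_all() == [("a", "b"), ("b", "c")]
        assert comp.edges_unique_to("x") == []

    def test_disjoint_networks_union_with_singleton_labels(self):
        a = RankedEdgeList([("a", "b", 0.9)], directed=False)
        b = RankedEdgeList([("c", "d", 0.8)], directed=False)
        comp = compare_networks({"na": a, "nb": b})
        assert comp.edges_in_all() == []
        assert comp.edges_unique_to("na") == [("a", "b")]
        assert comp.edges_unique_to("nb") == [("c", "d")]

    def test_orthologous_edge_shared_through_metagenes(self):
        table = build_metagenes(
            {("M", "L"): {("m1", "l1"), ("m2", "l2")}}
        )
        m_net = RankedEdgeList([("m1", "m2", 0.9), ("m1", "m9", 0.5)], directed=False)
        l_net = RankedEdgeList([("l1", "l2", 0.8)], directed=False)
        comp = compare_networks(
            {"med": m_net, "lot": l_net}, id_map=table, species_of={"med": "M", "lot": "L"}
        )
        assert len(comp.edges_in_all()) == 1
        assert comp.n_untranslated["med"] == 1  # m9 has no metagene

    def test_requires_two_networks(self):
        with pytest.raises(ValueError):
            compare_networks({"only": RankedEdgeList([("a", "b", 1.0)], directed=False)})


class TestGoEnrichment:
    def test_proportional_term_not_enriched(self):
        universe = {f"g{i}" for i in range(20)}
        subnet = {f"g{i}" for i in range(10)}
        annot = AnnotationTable({f"g{i}": {"T"} for i in range(0, 20, 2)})
        df = go_enrichment(subnet, universe, annot)
        assert df.loc[0, "chi2"] == pytest.approx(0.0)
        assert df.loc[0, "pvalue"] == pytest.approx(1.0)

    def test_hand_computed_extreme_table(self):
        # 2x2 table (10, 0 / 0, 10): chi2 = N = 20
        universe = {f"g{i}" for i in range(20)}
        subnet = {f"g{i}" for i in range(10)}
        annot = AnnotationTable({f"g{i}": {"T"} for i in range(10)})
        df = go_enrichment(subnet, universe, annot)
        assert df.loc[0, "chi2"] == pytest.approx(20.0)
        assert df.loc[0, "pvalue"] == pytest.approx(stats.chi2.sf(20, 1), rel=1e-6)
        assert df.loc[0, "pvalue"] == pytest.approx(7.7e-6, rel=0.01)
        assert df.loc[0, "direction"] == "enriched"

    def test_unannotated_subnet_reports_depletion(self):
        universe = {f"g{i}" for i in range(20)}
        subnet = {f"g{i}" for i in range(10)}
        annot = AnnotationTable({f"g{i}": {"T"} for i in range(10, 18)})
        df = go_enrichment(subnet, universe, annot)
        assert df.loc[0, "in_subnet_with_term"] == 0
        assert df.loc[0, "direction"] == "depleted"

    def test_zero_marginal_term_skipped_and_bh_added(self):
        universe = {f"g{i}" for i in range(10)}
        subnet = {"g0", "g1"}
        annot = AnnotationTable({"g0": {"T1"}, "zz": {"T2"}})  # T2 absent from universe
        df = go_enrichment(subnet, universe, annot)
        assert list(df["term"]) == ["T1"]
        assert "pvalue_bh" in df.columns

    def test_subnet_must_be_subset(self):
        with pytest.raises(ValueError):
            go_enrichment({"x"}, {"y"}, AnnotationTable({"y": {"T"}}))
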