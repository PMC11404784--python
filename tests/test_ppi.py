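"""PPI networks: order semantics, hub scoring, enrichment delegation, export."""

import math

import networkx as nx
import numpy as np
import pytest

from pathkit import ppi
from pathkit.errors import ValidationError
from pathkit.io import GeneSet, GeneSetDatabase, InteractionTable


SEEDS = {"a", "b", "c"}


class TestOrderSemantics:
    def test_zero_order_induces_on_seeds(self, toy_interactions):
        net = ppi.build_ppi_network(SEEDS, toy_interactions, order="zero")
        assert net.nodes == {"a", "b", "c"}
        assert net.edges == {("a", "b"), ("b", "c")}

    def test_first_order_adds_neighbours_and_their_edges(self, toy_interactions):
        net = ppi.build_ppi_network(SEEDS, toy_interactions, order="first")
        assert net.nodes == {"a", "b", "c", "d", "x"}
        assert net.edges == {("a", "b"), ("b", "c"), ("c", "d"), ("a", "x"), ("c", "x")}

    def test_minimum_order_trims_single_seed_interactors(self, toy_interactions):
        net = ppi.build_ppi_network(SEEDS, toy_interactions, order="minimum")
        # d touches only seed c -> removed; x touches seeds a and c -> kept
        assert net.nodes == {"a", "b", "c", "x"}
        assert net.edges == {("a", "b"), ("b", "c"), ("a", "x"), ("c", "x")}

    def test_order_containment_on_random_graphs(self):
        rng = np.random.default_rng(0)
        for trial in range(60):
            g = nx.gnp_random_graph(
                int(rng.integers(6, 30)), 0.15, seed=int(rng.integers(1 << 30))
            )
            g = nx.relabel_nodes(g, {i: f"n{i}" for i in g.nodes})
            if g.number_of_edges() == 0:
                continue
            inter = InteractionTable(edges=[tuple(sorted(e)) for e in g.edges])
            nodes = sorted(g.nodes)
            seeds = set(rng.choice(nodes, size=max(1, len(nodes) // 4), replace=False))
            if not (seeds & inter.nodes()):
                continue
            nets = {
                o: ppi.build_ppi_network(seeds, inter, order=o)
                for o in ("zero", "first", "minimum")
            }
            assert nets["zero"].nodes <= nets["minimum"].nodes <= nets["first"].nodes
            # every retained minimum-order interactor keeps >= 2 seed edges
            mg = nets["minimum"].graph
            present_seeds = seeds & set(g.nodes)
            for v in mg.nodes:
                if mg.nodes[v]["role"] == "interactor":
                    k = sum(1 for nb in g.neighbors(v) if nb in present_seeds)
                    assert k >= 2
            # edge provenance
            for net in nets.values():
                assert net.edges <= set(inter.edges)

    def test_absent_seeds_dropped_with_report(self, toy_interactions):
        net = ppi.build_ppi_network({"a", "zz"}, toy_interactions, order="zero")
        assert net.dropped_seeds == ("zz",)
        assert net.dropped_seed_count == 1

    def test_all_seeds_absent_is_error(self, toy_interactions):
        with pytest.raises(ValidationError):
            ppi.build_ppi_network({"zz"}, toy_interactions, order="zero")

    def test_unknown_order_rejected(self, toy_interactions):
        with pytest.raises(ValidationError):
            ppi.build_ppi_network(SEEDS, toy_interactions, order="second")

    def test_isolated_seed_removed_and_counted(self, toy_interactions):
        net = ppi.build_ppi_network({"a", "b", "e"}, toy_interactions, order="zero")
        assert "e" not in net.nodes
        assert net.isolated_removed == 1

    def test_deg_attributes_joined(self, toy_interactions, six_gene_table):
        tbl = six_gene_table
        tbl.data.loc[0, "gene_id"] = "a"  # rename g1 -> a for the join
        net = ppi.build_ppi_network(SEEDS, toy_interactions, order="zero",
                                    deg_table=tbl)
        assert net.graph.nodes["a"]["log2_fc"] == 1.0


class TestHubScoring:
    def test_star_centre_is_the_hub(self):
        inter = InteractionTable(edges=[("h", f"l{i}") for i in range(1, 5)])
        net = ppi.build_ppi_network({"h", "l1", "l2", "l3", "l4"}, inter, "zero")
        ppi.score_hubs(net, measure="betweenness", top_n=1)
        hubs = {v for v in net.graph.nodes if net.graph.nodes[v]["is_hub"]}
        assert hubs == {"h"}

    def test_path_midpoint_has_max_betweenness(self):
        inter = InteractionTable(edges=[("a", "b"), ("b", "c"), ("c", "d"), ("d", "e")])
        net = ppi.build_ppi_network(set("abcde"), inter, "zero")
        ppi.score_hubs(net, top_n=1)
        assert net.graph.nodes["c"]["is_hub"]

    def test_tie_broken_by_lexicographic_gene_id(self):
        # 4-cycle: all nodes tied on betweenness and degree
        inter = InteractionTable(edges=[("a", "b"), ("b", "c"), ("c", "d"), ("a", "d")])
        net = ppi.build_ppi_network(set("abcd"), inter, "zero")
        ppi.score_hubs(net, top_n=1)
        hubs = {v for v in net.graph.nodes if net.graph.nodes[v]["is_hub"]}
        assert hubs == {"a"}

    def test_top_n_exceeding_nodes_flags_all_with_warning(self):
        inter = InteractionTable(edges=[("a", "b")])
        net = ppi.build_ppi_network({"a", "b"}, inter, "zero")
        with pytest.warns(UserWarning):
            ppi.score_hubs(net, top_n=10)
        assert all(net.graph.nodes[v]["is_hub"] for v in net.graph.nodes)

    def test_determinism(self, toy_interactions):
        a = ppi.build_ppi_network(SEEDS, toy_interactions, "first")
        b = ppi.build_ppi_network(SEEDS, toy_interactions, "first")
        ppi.score_hubs(a)
        ppi.score_hubs(b)
        assert a.nodes == b.nodes and a.edges == b.edges
        assert {v: a.graph.nodes[v]["is_hub"] for v in a.nodes} == \
               {v: b.graph.nodes[v]["is_hub"] for v in b.nodes}


class TestEnrichAndSubnet:
    def test_delegation_matches_direct_hypergeometric(self):
        genes = [f"u{i}" for i in range(10)]
        db = GeneSetDatabase(
            [GeneSet("P1", "one", frozenset(genes[:3])),
             GeneSet("P2", "two", frozenset(genes[3:10]))]
        )
        inter = InteractionTable(edges=[(genes[0], genes[1]), (genes[1], genes[2])])
        net = ppi.build_ppi_network(set(genes[:3]), inter, "zero")
        res = ppi.enrich_network(net, db, method="ora")
        row = res[res.set_id == "P1"].iloc[0]
        assert (row.k, row.K, row.n, row.N) == (3, 3, 3, 10)
        assert row.p_value == pytest.approx(1 / 120, abs=1e-12)
        assert (res["direction"] == "all").all()

    def test_gsea_rejected_for_node_sets(self, toy_interactions, toy_pair_db):
        net = ppi.build_ppi_network(SEEDS, toy_interactions, "zero")
        with pytest.raises(ValidationError):
            ppi.enrich_network(net, toy_pair_db, method="gsea")

    def test_subnetwork_induces_and_preserves_roles(self, toy_interactions):
        net = ppi.build_ppi_network(SEEDS, toy_interactions, "first")
        sub = ppi.extract_subnetwork(net, {"a", "b", "z"})
        assert sub.nodes == {"a", "b"}
        assert sub.graph.nodes["a"]["role"] == "seed"

    def test_subnetwork_identity_when_pathway_covers_all(self, toy_interactions):
        net = ppi.build_ppi_network(SEEDS, toy_interactions, "zero")
        sub = ppi.extract_subnetwork(net, net.nodes)
        assert sub.nodes == net.nodes and sub.edges == net.edges

    def test_empty_intersection_is_error(self, toy_interactions):
        net = ppi.build_ppi_network(SEEDS, toy_interactions, "zero")
        with pytest.raises(ValidationError, match="mypath"):
            ppi.extract_subnetwork(net, {"zz"}, pathway_name="mypath")


class TestSerialisation:
    def test_graphml_roundtrip(self, toy_interactions, tmp_path):
        net = ppi.build_ppi_network(SEEDS, toy_interactions, "minimum")
        ppi.score_hubs(net)
        p = tmp_path / "n.graphml"
        net.to_graphml(p)
        back = ppi.PPINetwork.from_graphml(p)
        assert back.nodes == net.nodes and back.edges == net.edges
        assert back.order == "minimum"
        for v in net.nodes:
            assert back.graph.nodes[v]["role"] == net.graph.nodes[v]["role"]
            assert back.graph.nodes[v]["is_hub"] == net.graph.nodes[v]["is_hub"]

    def test_tsv_export_tables(self, toy_interactions, tmp_path):
        net = ppi.build_ppi_network(SEEDS, toy_interactions, "zero")
        np_, ep = tmp_path / "nodes.tsv", tmp_path / "edges.tsv"
        net.to_tsv(np_, ep)
        import pandas as pd
        nodes = pd.read_csv(np_, sep="\t")
        edges = pd.read_csv(ep, sep="\t")
        assert set(nodes["gene_id"]) == net.nodes
        assert len(edges) == len(net.edges)
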