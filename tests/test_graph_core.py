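"""Network construction, filtering, and centrality measures."""

import math

import networkx as nx
import pytest

from interactoscope import graph_core, io
from interactoscope.graph_core import (
    ACCEPT_ALL,
    FormatError,
    InteractionRecord,
    build_induced_network,
    centrality_table,
    largest_connected_component,
    read_edge_table,
    read_psimitab,
    read_protein_list,
    semilocal_centrality,
)


def _write_edge_tsv(path, rows):
    lines = ["gene_a\tgene_b\tinteraction_type\tsource"]
    lines += ["\t".join(r) for r in rows]
    path.write_text("\n".join(lines) + "\n")


class TestReadEdgeTable:
    ROWS = [
        ("A", "B", "direct", "db1"),
        ("B", "A", "direct", "db2"),
        ("C", "C", "direct", "db1"),
        ("A", "C", "colocalization", "db1"),
    ]

    def test_type_filter_dedup_and_self_loops(self, tmp_path):
        f = tmp_path / "e.tsv"
        _write_edge_tsv(f, self.ROWS)
        recs = read_edge_table(f, {"direct"})
        assert [r.pair for r in recs] == [("A", "B")]
        assert recs[0].source == "db1"  # first source retained

    def test_accept_all_sentinel(self, tmp_path):
        f = tmp_path / "e.tsv"
        _write_edge_tsv(f, self.ROWS)
        assert sorted(r.pair for r in read_edge_table(f, ACCEPT_ALL)) == [("A", "B"), ("A", "C")]

    def test_missing_columns_is_format_error(self, tmp_path):
        f = tmp_path / "bad.tsv"
        f.write_text("gene_a\tgene_b\nA\tB\n")
        with pytest.raises(FormatError, match="interaction_type"):
            read_edge_table(f)

    def test_empty_result_is_empty_list(self, tmp_path):
        f = tmp_path / "e.tsv"
        _write_edge_tsv(f, self.ROWS)
        assert read_edge_table(f, {"never-used-type"}) == []

    def test_round_trip_through_writer(self, tmp_path):
        g = nx.Graph([("A", "B"), ("B", "C"), ("A", "D"), ("C", "D")])
        f = tmp_path / "rt.tsv"
        io.write_edge_table(g, f)
        recs = read_edge_table(f, ACCEPT_ALL)
        assert sorted(r.pair for r in recs) == sorted(tuple(sorted(e)) for e in g.edges)


def test_read_psimitab_extracts_mi_terms(tmp_path):
    line = "\t".join(
        ["uniprotkb:AAA", "uniprotkb:BBB"] + ["-"] * 9
        + ['psi-mi:"MI:0407"(direct interaction)', 'psi-mi:"MI:0469"(IntAct)', "-"]
    )
    f = tmp_path / "x.mitab"
    f.write_text(line + "\n")
    recs = read_psimitab(f, {"MI:0407"})
    assert len(recs) == 1 and recs[0].pair == ("AAA", "BBB")
    assert read_psimitab(f, {"MI:0915"}) == []


def test_read_protein_list_normalizes_and_dedups(tmp_path):
    f = tmp_path / "p.txt"
    f.write_text("# header\nsrcin1\nSRC  # inline comment\nSRCIN1\n\n")
    assert read_protein_list(f) == ["SRCIN1", "SRC"]


class TestBuildInducedNetwork:
    def test_edges_restricted_to_listed_proteins(self):
        recs = [InteractionRecord("A", "B", "direct"), InteractionRecord("A", "D", "direct")]
        net = build_induced_network(["A", "B", "C"], recs)
        assert set(net.nodes) == {"A", "B", "C"}
        assert set(map(frozenset, net.edges)) == {frozenset({"A", "B"})}

    def test_isolated_single_protein(self):
        net = build_induced_network(["A"], [])
        assert set(net.nodes) == {"A"} and net.number_of_edges() == 0

    def test_planted_graph_identity(self):
        from interactoscope.synthetic_data import planted_partition_graph

        net, _ = planted_partition_graph(40, 2, 0.4, 0.02, seed=3)
        recs = [InteractionRecord(a, b, "direct") for a, b in net.edges]
        rebuilt = build_induced_network(net.nodes, recs)
        assert set(map(frozenset, rebuilt.edges)) == set(map(frozenset, net.edges))


class TestLargestConnectedComponent:
    def test_picks_bigger_component(self):
        g = nx.Graph()
        nx.add_path(g, ["A", "B", "C", "D", "E"])
        nx.add_path(g, ["X", "Y", "Z"])
        assert set(largest_connected_component(g).nodes) == {"A", "B", "C", "D", "E"}

    def test_connected_graph_is_identity(self, path4):
        assert set(largest_connected_component(path4).nodes) == set(path4.nodes)

    def test_tie_broken_by_smallest_symbol(self):
        g = nx.Graph([("B", "C"), ("A", "D")])
        assert set(largest_connected_component(g).nodes) == {"A", "D"}

    def test_matches_union_find_oracle(self):
        rng = nx.gnp_random_graph(50, 0.03, seed=11)
        g = nx.relabel_nodes(rng, {i: f"G{i:03d}" for i in rng.nodes})
        # independent union-find
        parent = {v: v for v in g.nodes}

        def find(v):
            while parent[v] != v:
                parent[v] = parent[parent[v]]
                v = parent[v]
            return v

        for a, b in g.edges:
            parent[find(a)] = find(b)
        comps = {}
        for v in g.nodes:
            comps.setdefault(find(v), set()).add(v)
        biggest = sorted(comps.values(), key=lambda c: (-len(c), min(c)))[0]
        assert set(largest_connected_component(g).nodes) == biggest


def _brute_force_semilocal(g):
    """Independent two-hop BFS oracle for Cl(v)."""
    def n2(w):
        return len({x for x in g.nodes if x != w and nx.shortest_path_length(g, w, x) <= 2})

    q = {u: sum(n2(w) for w in g[u]) for u in g}
    return {v: sum(q[u] for u in g[v]) for v in g}


class TestSemilocalCentrality:
    @pytest.mark.parametrize(
        "edges, raw, norm",
        [
            ([("A", "B"), ("B", "C"), ("C", "D")],
             {"A": 5, "B": 8, "C": 8, "D": 5}, {"A": 0, "B": 1, "C": 1, "D": 0}),
            ([("A", "B"), ("B", "C"), ("A", "C"), ("A", "D")],
             {"A": 15, "B": 15, "C": 15, "D": 9}, {"A": 1, "B": 1, "C": 1, "D": 0}),
        ],
    )
    def test_hand_examples(self, edges, raw, norm):
        res = semilocal_centrality(nx.Graph(edges))
        assert {v: r for v, (r, _) in res.items()} == raw
        assert {v: n for v, (_, n) in res.items()} == norm

    def test_symmetric_star_degenerates_to_half(self):
        res = semilocal_centrality(nx.star_graph(4))
        assert all(r == 16 and n == 0.5 for r, n in res.values())

    def test_single_node_is_error(self):
        with pytest.raises(ValueError):
            semilocal_centrality(nx.Graph([("A", "A")]))

    def test_agrees_with_brute_force_oracle_on_random_graphs(self):
        checked = 0
        for s in range(200):
            g = nx.gnp_random_graph(5 + s % 26, 0.25, seed=s)
            if not (g.number_of_nodes() >= 2 and nx.is_connected(g)):
                continue
            res = semilocal_centrality(g)
            oracle = _brute_force_semilocal(g)
            assert {v: r for v, (r, _) in res.items()} == pytest.approx(oracle)
            assert all(0.0 <= n <= 1.0 for _, n in res.values())
            checked += 1
        assert checked >= 100


class TestCentralityTable:
    def test_path_degree_and_betweenness(self):
        t = centrality_table(nx.path_graph(["A", "B", "C"]))
        assert t["degree"].to_dict() == {"A": 1, "B": 2, "C": 1}
        assert t["betweenness"].to_dict() == {"A": 0.0, "B": 1.0, "C": 0.0}
        assert t.loc["B", "mean_shortest_path"] == 1.0

    def test_complete_graph_clustering_coefficient(self):
        t = centrality_table(nx.complete_graph(4))
        assert (t["clustering_coefficient"] == 1.0).all()

    def test_pagerank_sums_to_one(self, two_cliques):
        g, _, _ = two_cliques
        assert centrality_table(g)["pagerank"].sum() == pytest.approx(1.0, abs=1e-9)

    def test_disconnected_input_rejected(self):
        g = nx.Graph([("A", "B"), ("C", "D")])
        with pytest.raises(ValueError, match="LCC"):
            centrality_table(g)
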