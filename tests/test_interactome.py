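"""Graph parsing, centrality computation and target prioritization."""

import math
import itertools

import networkx as nx
import numpy as np
import pytest

from dtiscreen.interactome import (
    CentralityRecord,
    InteractomeGraph,
    ParseError,
    betweenness_centrality,
    centrality_records,
    parse_string_links,
    prioritize_targets,
    read_shortlist,
    restrict_to_nodes,
    subgraph_centrality,
    write_shortlist,
)
from dtiscreen.synthetic_fixtures import make_graph, write_string_links


# --- independent oracles ----------------------------------------------------

def sc_series_oracle(graph, order=60):
    """Truncated closed-walk series sum_{k=0..order} (A^k)_uu / k!."""
    nodes = sorted(graph.nodes)
    adj = nx.to_numpy_array(graph, nodelist=nodes, weight=None)
    term = np.eye(len(nodes))
    diag = np.ones(len(nodes))
    for k in range(1, order + 1):
        term = term @ adj
        diag = diag + np.diag(term) / math.factorial(k)
    return dict(zip(nodes, diag))


def bc_enumeration_oracle(graph):
    """Exhaustive shortest-path enumeration of normalized betweenness."""
    nodes = sorted(graph.nodes)
    n = len(nodes)
    result = {v: 0.0 for v in nodes}
    if n < 3:
        return result
    for s, t in itertools.combinations(nodes, 2):
        try:
            paths = list(nx.all_shortest_paths(graph, s, t))
        except nx.NetworkXNoPath:
            continue
        sigma = len(paths)
        for v in nodes:
            if v in (s, t):
                continue
            through = sum(1 for p in paths if v in p[1:-1])
            result[v] += through / sigma
    norm = 2.0 / ((n - 1) * (n - 2))
    return {v: val * norm for v, val in result.items()}


# --- parsing ----------------------------------------------------------------

class TestParseStringLinks:
    def test_dedup_and_self_loop_drop(self, tmp_path):
        f = tmp_path / "links.txt"
        f.write_text("a b 900\nb a 900\na a 500\n")
        g = parse_string_links(f)
        assert set(g.nodes) == {"a", "b"}
        assert g.number_of_edges() == 1

    def test_ring_round_trip(self, tmp_path):
        ring = make_graph("ring", 5, seed=0)
        f = tmp_path / "ring.txt"
        write_string_links(ring, f)
        g = parse_string_links(f)
        assert set(g.nodes) == set(ring.nodes)
        assert set(map(frozenset, g.edges)) == set(map(frozenset, ring.edges))

    def test_min_score_threshold_is_inclusive(self, tmp_path):
        f = tmp_path / "links.txt"
        f.write_text("a b 650\nb c 700\nc d 900\n")
        g = parse_string_links(f, min_score=700)
        assert g.number_of_edges() == 2

    def test_header_line_skipped(self, tmp_path):
        f = tmp_path / "links.txt"
        f.write_text("protein1 protein2 combined_score\na b 900\n")
        assert parse_string_links(f).number_of_edges() == 1

    def test_malformed_line_names_line_number(self, tmp_path):
        f = tmp_path / "links.txt"
        f.write_text("a b 900\nonly_one_column\n")
        with pytest.raises(ParseError, match="line 2"):
            parse_string_links(f)

    def test_empty_file_yields_empty_graph(self, tmp_path):
        f = tmp_path / "links.txt"
        f.write_text("")
        g = parse_string_links(f)
        assert g.number_of_nodes() == 0


class TestRestrictToNodes:
    def test_ring_to_path(self):
        ring = make_graph("ring", 5, seed=0)
        keep = sorted(ring.nodes)[:3]  # consecutive on the ring
        sub = restrict_to_nodes(ring, keep)
        assert sub.number_of_nodes() == 3
        assert sub.number_of_edges() == 2

    def test_keep_all_is_identity(self):
        g = make_graph("random", 15, seed=1)
        sub = restrict_to_nodes(g, set(g.nodes))
        assert set(sub.nodes) == set(g.nodes)
        assert set(map(frozenset, sub.edges)) == set(map(frozenset, g.edges))

    def test_empty_keep(self):
        g = make_graph("ring", 5, seed=0)
        assert restrict_to_nodes(g, set()).number_of_nodes() == 0


# --- subgraph centrality ----------------------------------------------------

class TestSubgraphCentrality:
    def test_isolated_node_is_one(self):
        g = InteractomeGraph()
        g.add_node("x")
        assert subgraph_centrality(g)["x"] == pytest.approx(1.0)

    def test_k2_equals_cosh_one(self):
        g = InteractomeGraph()
        g.add_edge("a", "b")
        sc = subgraph_centrality(g)
        for v in "ab":
            assert sc[v] == pytest.approx(math.cosh(1.0), rel=1e-9)

    def test_k3_closed_form(self):
        g = make_graph("complete", 3)
        expected = math.exp(2) / 3 + 2 * math.exp(-1) / 3
        for v, val in subgraph_centrality(g).items():
            assert val == pytest.approx(expected, rel=1e-9)

    def test_matches_series_oracle_on_random_graphs(self):
        rng = np.random.default_rng(42)
        for trial in range(25):
            n = int(rng.integers(2, 51))
            g = make_graph("random", n, seed=int(rng.integers(0, 10_000)))
            sc = subgraph_centrality(g)
            oracle = sc_series_oracle(g)
            for v in g.nodes:
                assert sc[v] == pytest.approx(oracle[v], rel=1e-6)

    def test_adding_edge_never_decreases_endpoint_sc(self):
        rng = np.random.default_rng(3)
        for _ in range(10):
            g = make_graph("random", 12, seed=int(rng.integers(0, 1000)))
            non_edges = [
                (u, v) for u, v in itertools.combinations(sorted(g.nodes), 2)
                if not g.has_edge(u, v)
            ]
            if not non_edges:
                continue
            u, v = non_edges[int(rng.integers(len(non_edges)))]
            before = subgraph_centrality(g)
            g.add_edge(u, v)
            after = subgraph_centrality(g)
            assert after[u] >= before[u] - 1e-12
            assert after[v] >= before[v] - 1e-12


# --- betweenness centrality -------------------------------------------------

class TestBetweennessCentrality:
    def test_complete_graph_all_zero(self):
        for n in (3, 5, 8):
            g = make_graph("complete", n)
            assert all(v == 0.0 for v in betweenness_centrality(g).values())

    def test_path_of_three(self):
        g = InteractomeGraph()
        g.add_edge("a", "b")
        g.add_edge("b", "c")
        bc = betweenness_centrality(g)
        assert bc["b"] == pytest.approx(1.0)
        assert bc["a"] == bc["c"] == 0.0

    def test_star_center(self):
        g = make_graph("star", 5)
        bc = betweenness_centrality(g)
        center = sorted(g.nodes)[0]
        assert bc[center] == pytest.approx(1.0)
        assert all(bc[v] == 0.0 for v in g.nodes if v != center)

    def test_small_graphs_match_enumeration_oracle(self):
        rng = np.random.default_rng(11)
        for trial in range(20):
            n = int(rng.integers(2, 8))
            g = make_graph("random", n, seed=int(rng.integers(0, 10_000)), p=0.4)
            bc = betweenness_centrality(g)
            oracle = bc_enumeration_oracle(g)
            for v in g.nodes:
                assert bc[v] == pytest.approx(oracle[v], abs=1e-10)

    def test_fewer_than_three_nodes(self):
        g = InteractomeGraph()
        g.add_edge("a", "b")
        assert betweenness_centrality(g) == {"a": 0.0, "b": 0.0}


def test_relabeling_permutes_both_centralities():
    g = make_graph("random", 20, seed=5)
    mapping = {n: f"X{n}" for n in g.nodes}
    h = InteractomeGraph()
    h.add_nodes_from(mapping.values())
    h.add_edges_from((mapping[u], mapping[v]) for u, v in g.edges)
    sc_g, bc_g = subgraph_centrality(g), betweenness_centrality(g)
    sc_h, bc_h = subgraph_centrality(h), betweenness_centrality(h)
    for n in g.nodes:
        assert sc_h[mapping[n]] == pytest.approx(sc_g[n], rel=1e-12)
        assert bc_h[mapping[n]] == pytest.approx(bc_g[n], abs=1e-12)


# --- prioritization ---------------------------------------------------------

TOP_TARGETS = [
    ("SACOL2213", 1.85e23, 0.0329),
    ("SACOL0591", 2.76e23, 0.0198),
    ("SACOL0588", 1.17e23, 0.0178),
    ("SACOL2675", 1.01e23, 0.0128),
    ("SACOL1292", 2.65e23, 0.0112),
    ("SACOL0593", 2.82e23, 0.0093),
    ("SACOL2234", 3.29e23, 0.0049),
    ("SACOL2233", 3.11e23, 0.0047),
    ("SACOL2207", 2.94e23, 0.0046),
    ("SACOL0545", 1.06e23, 0.0045),
]


class TestPrioritizeTargets:
    def test_published_shortlist_with_decoy(self):
        records = [CentralityRecord(p, sc, bc) for p, sc, bc in TOP_TARGETS]
        records.append(CentralityRecord("DECOY", 1.0e20, 0.5))  # below SC cut
        shortlist = prioritize_targets(records, sc_min=1e23, k=10)
        assert [r.protein_id for r in shortlist] == [p for p, _, _ in TOP_TARGETS]
        assert shortlist[0].protein_id == "SACOL2213"
        assert shortlist[0].bc == pytest.approx(0.0329)
        assert shortlist[-1].protein_id == "SACOL0545"
        assert shortlist[-1].bc == pytest.approx(0.0045)

    def test_empty_input(self):
        assert prioritize_targets([], sc_min=1.0, k=10) == []

    def test_bc_tie_broken_by_sc_descending(self):
        a = CentralityRecord("a", 2e23, 0.01)
        b = CentralityRecord("b", 5e23, 0.01)
        assert prioritize_targets([a, b], sc_min=1e23, k=2)[0].protein_id == "b"

    def test_sc_filter_is_strict(self):
        rec = CentralityRecord("edge", 1e23, 0.9)
        assert prioritize_targets([rec], sc_min=1e23, k=5) == []


def test_shortlist_round_trip(tmp_path):
    records = [CentralityRecord(p, sc, bc) for p, sc, bc in TOP_TARGETS[:3]]
    path = tmp_path / "shortlist.tsv"
    write_shortlist(records, path)
    back = read_shortlist(path)
    assert [r.protein_id for r in back] == [r.protein_id for r in records]
    for orig, rt in zip(records, back):
        assert rt.sc == pytest.approx(orig.sc, rel=1e-2)   # 3 sig digits
        assert rt.bc == pytest.approx(orig.bc, abs=5e-5)   # 4 decimals
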