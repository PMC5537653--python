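import networkx as nx
import numpy as np
import pytest

from oracles import dfs_components, reciprocated_edges
from viromenet import reference
from viromenet.network import (
    EdgeThresholds,
    build_network,
    connected_components,
    parse_distribution,
    render_distribution,
    round_half_up,
    summarize,
    summary_from_distribution,
)
from viromenet.similarity_engine import SimilarityHit, all_vs_all
from viromenet.synthetic_data import FamilySpec, SynthConfig, generate_dataset

from conftest import make_protein


def hit(q, s, evalue=1e-20, identity=90.0, coverage=90.0):
    return SimilarityHit(q, s, 100, 50.0, evalue, identity, coverage, 1, 10, 1, 10)


def two_proteins():
    return [make_protein("a", "MKLV" * 10), make_protein("b", "MKLV" * 10)]


class TestBuildNetwork:
    def test_reciprocation_required(self):
        proteins = two_proteins()
        hits = [hit("a", "b"), hit("b", "a", coverage=30.0)]  # b->a fails coverage
        net = build_network(hits, EdgeThresholds(), proteins)
        assert net.number_of_edges() == 0
        assert net.number_of_nodes() == 2  # isolated nodes retained

    def test_boundary_values_pass(self):
        proteins = two_proteins()
        hits = [hit("a", "b", evalue=1e-5, identity=50.0, coverage=50.0),
                hit("b", "a", evalue=1e-5, identity=50.0, coverage=50.0)]
        net = build_network(hits, EdgeThresholds(), proteins)
        assert net.has_edge("a", "b")

    def test_five_identical_proteins_make_k5(self):
        proteins = [make_protein(f"p{i}", "MAWNKQEDHL" * 8) for i in range(5)]
        net = build_network(all_vs_all(proteins), EdgeThresholds(), proteins)
        assert net.number_of_edges() == 10

    def test_edge_attributes_are_conservative_combination(self):
        proteins = two_proteins()
        hits = [hit("a", "b", evalue=1e-20, identity=95.0, coverage=80.0),
                hit("b", "a", evalue=1e-10, identity=90.0, coverage=70.0)]
        net = build_network(hits, EdgeThresholds(), proteins)
        data = net.edges["a", "b"]
        assert data["identity"] == 90.0
        assert data["evalue"] == 1e-10
        assert data["coverage"] == 70.0

    def test_unknown_node_in_hit_is_error(self):
        with pytest.raises(ValueError, match="unknown protein"):
            build_network([hit("a", "zzz")], EdgeThresholds(), two_proteins())

    def test_edge_set_equals_double_loop_oracle_on_synthetic_data(self):
        config = SynthConfig(
            seed=13,
            families=(
                FamilySpec("fa", ("P1", "P2", "P3", "P4"), 150, 90.0),
                FamilySpec("fb", ("P1", "P2", "P3"), 180, 90.0),
            ),
            n_singletons=5,
        )
        proteins, _ = generate_dataset(config)
        hits = all_vs_all(proteins)
        th = EdgeThresholds()
        net = build_network(hits, th, proteins)
        oracle = reciprocated_edges(hits, th.evalue_max, th.identity_min, th.coverage_min)
        assert set(map(frozenset, net.edges)) == oracle

    def test_relaxing_thresholds_never_removes_edges(self):
        config = SynthConfig(
            seed=21,
            families=(FamilySpec("fa", ("P1", "P2", "P3"), 150, 65.0),),
            n_singletons=4,
        )
        proteins, _ = generate_dataset(config)
        hits = all_vs_all(proteins)
        strict = build_network(hits, EdgeThresholds(1e-10, 60.0, 60.0), proteins)
        relaxed = build_network(hits, EdgeThresholds(1e-5, 50.0, 50.0), proteins)
        assert set(strict.edges) <= set(relaxed.edges)


class TestConnectedComponents:
    def test_edgeless_graph_gives_singletons(self):
        net = nx.Graph()
        net.add_nodes_from("abcd")
        partition = connected_components(net)
        assert sorted(partition.values()) == ["a", "b", "c", "d"]

    def test_path_plus_isolate(self):
        net = nx.Graph([("a", "b"), ("b", "c")])
        net.add_node("d")
        partition = connected_components(net)
        assert partition == {"a": "a", "b": "a", "c": "a", "d": "d"}

    def test_matches_dfs_oracle_on_random_graphs(self):
        for seed in range(10):
            g = nx.gnp_random_graph(200, 0.008, seed=seed)
            g = nx.relabel_nodes(g, {n: f"n{n:03d}" for n in g.nodes})
            partition = connected_components(g)
            mine = {frozenset(nodes) for nodes in _group(partition).values()}
            assert mine == dfs_components(list(g.nodes), list(g.edges))


def _group(partition):
    groups = {}
    for node, cid in partition.items():
        groups.setdefault(cid, set()).add(node)
    return groups


class TestSummarize:
    def test_published_census_reproduces_printed_statistics(self):
        """The printed subgraph-size census implies the clustered-node count and %."""
        distribution = parse_distribution(reference.SUBGRAPH_CENSUS)
        summary = summary_from_distribution(distribution, reference.N_SINGLETONS,
                                            n_edges=reference.N_EDGES)
        assert summary.n_clustered_nodes == 2437
        assert summary.n_multi_subgraphs == 666
        assert summary.n_nodes == 3688
        assert summary.pct_clustered == 66.1

    def test_all_singleton_network(self):
        net = nx.Graph()
        net.add_nodes_from("abc")
        summary = summarize(connected_components(net), net)
        assert summary.pct_clustered == 0.0
        assert summary.size_distribution == []
        assert summary.n_singletons == 3

    def test_single_triangle(self):
        net = nx.complete_graph(["a", "b", "c"])
        summary = summarize(connected_components(net), net)
        assert summary.pct_clustered == 100.0
        assert summary.size_distribution == [(3, 1)]

    def test_accounting_identities_on_synthetic_run(self, small_dataset):
        proteins, _ = small_dataset
        net = build_network(all_vs_all(proteins), EdgeThresholds(), proteins)
        summary = summarize(connected_components(net), net)
        assert sum(s * n for s, n in summary.size_distribution) == summary.n_clustered_nodes
        assert summary.n_clustered_nodes + summary.n_singletons == summary.n_nodes
        assert summary.n_edges >= summary.n_clustered_nodes - summary.n_multi_subgraphs


class TestDistributionStrings:
    def test_single_token(self):
        assert parse_distribution("2s:175n") == [(2, 175)]

    def test_empty_string(self):
        assert parse_distribution("") == []

    def test_malformed_token_named(self):
        with pytest.raises(ValueError, match="'2x:5n'"):
            parse_distribution("3s:1n, 2x:5n")

    def test_render_parse_round_trip_random(self):
        rng = np.random.default_rng(3)
        for _ in range(100):
            sizes = rng.choice(np.arange(2, 40), size=rng.integers(1, 10), replace=False)
            dist = sorted(((int(s), int(rng.integers(1, 300))) for s in sizes),
                          key=lambda t: -t[0])
            assert parse_distribution(render_distribution(dist)) == dist


def test_round_half_up_matches_printed_conventions():
    assert round_half_up(66.0791, 1) == 66.1
    assert round_half_up(72.3156, 2) == 72.32
    assert round_half_up(0.25, 1) == 0.3  # half-up, not banker's
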