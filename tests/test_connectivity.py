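import itertools

import numpy as np
import pytest

from litmap.network import (
    CooccurrenceMatrix,
    NetworkEdge,
    NetworkNode,
    ConnectivityNetwork,
    below_median_subnetwork,
    child_network,
    connectivity_matrix_frame,
    connectivity_network,
    cooccurrence_counts,
    median_connectivity,
    network_from_dict,
    network_to_dict,
    read_matrix_csv,
    top_k_pairs,
    write_matrix_csv,
)
from litmap.scheme import CHILD

from conftest import make_scheme, make_tags


def brute_force_counts(tagsets, names):
    """Independent double-loop oracle for the co-occurrence matrix."""
    n = len(names)
    counts = np.zeros((n, n), dtype=int)
    for tags in tagsets:
        for i, a in enumerate(names):
            for j, b in enumerate(names):
                if i == j:
                    counts[i, i] += a in tags
                elif a in tags and b in tags:
                    counts[i, j] += 1
    return counts


def random_tagsets(rng, names, n_articles, p=0.35):
    return [{name for name in names if rng.random() < p} for _ in range(n_articles)]


def network_from_connectivities(values):
    """A star network whose edge connectivities are exactly `values`."""
    nodes = [NetworkNode("Hub", "X", 1, float(sum(values)))]
    edges = []
    for i, value in enumerate(values):
        name = f"N{i}"
        nodes.append(NetworkNode(name, "X", 1, float(value)))
        src, dst = sorted(("Hub", name))
        edges.append(NetworkEdge(src, dst, 1, float(value)))
    return ConnectivityNetwork(nodes=nodes, edges=sorted(edges, key=lambda e: e.pair),
                               median_connectivity=None)


class TestCooccurrenceCounts:
    def test_single_article_three_concepts(self):
        tags = make_tags({"A", "B", "C"})
        matrix = cooccurrence_counts(tags, ["A", "B", "C"])
        assert np.array_equal(matrix.counts, np.array([[1, 1, 1], [1, 1, 1], [1, 1, 1]]))

    def test_disjoint_concepts_have_zero_pair_count(self):
        tags = make_tags({"A"}, {"B"}, {"A"})
        matrix = cooccurrence_counts(tags, ["A", "B"])
        assert matrix.counts[0, 1] == 0
        assert matrix.counts[0, 0] == 2 and matrix.counts[1, 1] == 1

    def test_matches_double_loop_oracle_on_300_articles(self):
        rng = np.random.default_rng(17)
        names = [f"C{i}" for i in range(6)]
        tagsets = random_tagsets(rng, names, 300)
        matrix = cooccurrence_counts(make_tags(*tagsets), names)
        assert np.array_equal(matrix.counts, brute_force_counts(tagsets, names))

    def test_unknown_node_name_fatal_with_scheme(self):
        scheme = make_scheme({"A": ["x"]})
        with pytest.raises(KeyError, match="Nope"):
            cooccurrence_counts(make_tags({"A"}), ["Nope"], scheme=scheme)

    def test_invariants_hold_on_random_cases(self):
        rng = np.random.default_rng(99)
        names = ["A", "B", "C", "D"]
        for _ in range(200):
            tagsets = random_tagsets(rng, names, int(rng.integers(0, 40)))
            matrix = cooccurrence_counts(make_tags(*tagsets), names)
            counts = matrix.counts
            assert np.array_equal(counts, counts.T)
            diag = np.diag(counts)
            for i, j in itertools.combinations(range(len(names)), 2):
                assert 0 <= counts[i, j] <= min(diag[i], diag[j])

    def test_invalid_matrices_rejected(self):
        with pytest.raises(ValueError, match="symmetric"):
            CooccurrenceMatrix(["A", "B"], np.array([[1, 1], [0, 1]]))
        with pytest.raises(ValueError, match="exceeds"):
            CooccurrenceMatrix(["A", "B"], np.array([[1, 2], [2, 3]]))
        with pytest.raises(ValueError, match="non-negative"):
            CooccurrenceMatrix(["A", "B"], np.array([[1, -1], [-1, 1]]))


class TestConnectivityNetwork:
    def test_hand_computed_ratio(self):
        scheme = make_scheme({"A": [f"a{i}" for i in range(10)], "B": [f"b{i}" for i in range(5)]})
        matrix = CooccurrenceMatrix(["A", "B"], np.array([[4, 3], [3, 5]]))
        net = connectivity_network(matrix, scheme)
        assert len(net.edges) == 1
        assert net.edges[0].connectivity == pytest.approx(0.2, abs=0)
        assert net.edges[0].study_count == 3

    def test_zero_pair_count_means_no_edge(self):
        scheme = make_scheme({"A": ["x"], "B": ["y"]})
        matrix = CooccurrenceMatrix(["A", "B"], np.array([[2, 0], [0, 3]]))
        net = connectivity_network(matrix, scheme)
        assert net.edges == []
        assert {n.name for n in net.nodes} == {"A", "B"}  # isolated nodes kept

    def test_zero_keyword_node_excluded_with_warning(self, caplog):
        scheme = make_scheme({"A": ["x"], "B": ["y"], "Empty": []})
        matrix = CooccurrenceMatrix(["A", "B", "Empty"], np.zeros((3, 3), dtype=int))
        with caplog.at_level("WARNING"):
            net = connectivity_network(matrix, scheme)
        assert {n.name for n in net.nodes} == {"A", "B"}
        assert any("Empty" in rec.message for rec in caplog.records)

    def test_all_zero_matrix_gives_empty_edge_network(self):
        scheme = make_scheme({"A": ["x"], "B": ["y"]})
        net = connectivity_network(CooccurrenceMatrix(["A", "B"], np.zeros((2, 2), dtype=int)), scheme)
        assert net.edges == [] and net.median_connectivity is None

    def test_weighted_degree_matches_incident_sum_oracle(self):
        rng = np.random.default_rng(7)
        names = [f"C{i}" for i in range(5)]
        scheme = make_scheme({n: [f"{n}_kw{j}" for j in range(int(rng.integers(1, 6)))] for n in names})
        for _ in range(30):
            tagsets = random_tagsets(rng, names, 60)
            matrix = cooccurrence_counts(make_tags(*tagsets), names)
            net = connectivity_network(matrix, scheme)
            for node in net.nodes:
                incident = sum(e.connectivity for e in net.edges if node.name in e.pair)
                assert node.weighted_degree == pytest.approx(incident, abs=1e-12)

    def test_handshake_identity(self):
        rng = np.random.default_rng(21)
        names = [f"C{i}" for i in range(6)]
        scheme = make_scheme({n: [f"{n}{j}" for j in range(3)] for n in names})
        tagsets = random_tagsets(rng, names, 120)
        net = connectivity_network(cooccurrence_counts(make_tags(*tagsets), names), scheme)
        total_degree = sum(n.weighted_degree for n in net.nodes)
        total_edges = sum(e.connectivity for e in net.edges)
        assert total_degree == pytest.approx(2 * total_edges, abs=1e-12)

    def test_doubling_keyword_counts_halves_connectivity(self):
        rng = np.random.default_rng(5)
        names = ["A", "B", "C"]
        base = {n: [f"{n}{j}" for j in range(2 + i)] for i, n in enumerate(names)}
        doubled = {n: kws + [f"{kw}x" for kw in kws] for n, kws in base.items()}
        tagsets = random_tagsets(rng, names, 80)
        matrix = cooccurrence_counts(make_tags(*tagsets), names)
        net1 = connectivity_network(matrix, make_scheme(base))
        net2 = connectivity_network(matrix, make_scheme(doubled))
        for e1, e2 in zip(net1.edges, net2.edges):
            assert e2.connectivity == e1.connectivity / 2  # exact float halving
        for n1, n2 in zip(net1.nodes, net2.nodes):
            assert n2.weighted_degree == pytest.approx(n1.weighted_degree / 2, rel=1e-15)


class TestMedian:
    def test_odd_count(self):
        net = network_from_connectivities([0.1, 0.2, 0.4])
        assert median_connectivity(net) == pytest.approx(0.2)

    def test_even_count_midpoint(self):
        net = network_from_connectivities([0.1, 0.2])
        assert median_connectivity(net) == pytest.approx(0.15)

    def test_matches_sort_and_pick_oracle(self):
        rng = np.random.default_rng(13)
        values = list(rng.random(101))
        net = network_from_connectivities(values)
        assert median_connectivity(net) == pytest.approx(sorted(values)[50], abs=0)

    def test_empty_edge_set_errors(self):
        net = ConnectivityNetwork(nodes=[NetworkNode("A", "X", 1, 0.0)])
        with pytest.raises(ValueError, match="median undefined"):
            median_connectivity(net)


class TestBelowMedianSubnetwork:
    def test_strict_inequality_keeps_only_weakest(self):
        net = network_from_connectivities([0.1, 0.2, 0.4])
        sub = below_median_subnetwork(net)
        assert [e.connectivity for e in sub.edges] == [0.1]
        assert {n.name for n in sub.nodes} == set(sub.edges[0].pair)

    def test_all_equal_edges_give_empty_subnetwork(self):
        sub = below_median_subnetwork(network_from_connectivities([0.3, 0.3, 0.3]))
        assert sub.edges == [] and sub.nodes == []

    def test_partition_property(self):
        rng = np.random.default_rng(2)
        for _ in range(50):
            values = list(rng.random(int(rng.integers(1, 25))))
            net = network_from_connectivities(values)
            median = median_connectivity(net)
            sub = below_median_subnetwork(net)
            below = {id(e) for e in net.edges if e.connectivity < median}
            at_or_above = {id(e) for e in net.edges if e.connectivity >= median}
            assert below | at_or_above == {id(e) for e in net.edges}
            assert below & at_or_above == set()
            assert {id(e) for e in sub.edges} <= below
            assert len(sub.edges) == len(below)

    def test_degrees_recomputed_within_subnetwork(self):
        net = network_from_connectivities([0.1, 0.15, 0.4, 0.5])
        sub = below_median_subnetwork(net)
        hub = sub.node("Hub")
        assert hub.weighted_degree == pytest.approx(0.1 + 0.15, abs=1e-12)


class TestTopKPairs:
    def test_descending_order(self):
        net = network_from_connectivities([0.5, 0.3, 0.1])
        top = top_k_pairs(net, 2)
        assert [e.connectivity for e in top] == [0.5, 0.3]

    def test_tie_breaks_lexicographically(self):
        edges = [NetworkEdge("A", "C", 1, 0.5), NetworkEdge("A", "B", 1, 0.5)]
        nodes = [NetworkNode(n, "X", 1, 0.5) for n in "ABC"]
        net = ConnectivityNetwork(nodes=nodes, edges=edges)
        assert top_k_pairs(net, 1)[0].pair == ("A", "B")

    def test_matches_full_sort_oracle(self):
        rng = np.random.default_rng(31)
        for _ in range(25):
            values = list(rng.random(int(rng.integers(5, 30))))
            net = network_from_connectivities(values)
            top = top_k_pairs(net, 5)
            oracle = sorted(net.edges, key=lambda e: (-e.connectivity, e.pair))[:5]
            assert top == oracle

    def test_too_few_edges_reports_available_count(self):
        net = network_from_connectivities([0.1, 0.2])
        with pytest.raises(ValueError, match="2"):
            top_k_pairs(net, 5)


class TestChildNetwork:
    @pytest.fixture
    def family_scheme(self):
        return make_scheme(
            {"P": ["p0"], "Q": ["q0"], "Childless": ["z0"]},
            children={
                "P": {"P1": ["k1"], "P2": ["k2"], "P3": ["k3"]},
                "Q": {"Q1": ["k4"]},
            },
        )

    def test_three_child_network_matches_brute_force(self, family_scheme):
        rng = np.random.default_rng(8)
        child_names = ["P1", "P2", "P3"]
        tagsets = [
            {name for name in child_names if rng.random() < 0.5} for _ in range(100)
        ]
        tags = make_tags(*[{"P"}] * 100, children=dict(enumerate(tagsets)))
        net = child_network(tags, family_scheme, {"P"})
        assert set(net.node_names()) == set(child_names)
        oracle = brute_force_counts(tagsets, child_names)
        recomputed = cooccurrence_counts(tags, child_names, level=CHILD, scheme=family_scheme)
        assert np.array_equal(recomputed.counts, oracle)
        for e in net.edges:
            i, j = child_names.index(e.source), child_names.index(e.target)
            denominator = family_scheme.keyword_count(e.source) + family_scheme.keyword_count(e.target)
            assert e.connectivity == pytest.approx(oracle[i, j] / denominator)

    def test_childless_parents_give_empty_network(self, family_scheme, caplog):
        with caplog.at_level("WARNING"):
            net = child_network(make_tags({"Childless"}), family_scheme, {"Childless"})
        assert net.nodes == [] and net.edges == []

    def test_empty_parent_subset_is_error(self, family_scheme):
        with pytest.raises(ValueError):
            child_network([], family_scheme, set())

    def test_top_pair_drilldown_construction(self, family_scheme):
        tags = make_tags(
            *[{"P", "Q"}] * 10,
            children={i: {"P1", "Q1"} for i in range(10)},
        )
        parent_net = connectivity_network(
            cooccurrence_counts(tags, ["P", "Q", "Childless"]), family_scheme
        )
        strongest = top_k_pairs(parent_net, 1)
        subset = {name for e in strongest for name in e.pair}
        net = child_network(tags, family_scheme, subset)
        assert set(net.node_names()) == {"P1", "P2", "P3", "Q1"}
        edge = next(e for e in net.edges if e.pair == ("P1", "Q1"))
        assert edge.study_count == 10


class TestSerialization:
    def test_network_dict_round_trip(self):
        net = network_from_connectivities([0.1, 0.25])
        net.median_connectivity = 0.175
        assert network_from_dict(network_to_dict(net)) == net

    def test_matrix_csv_round_trip(self, tmp_path):
        matrix = cooccurrence_counts(make_tags({"A", "B"}, {"A"}), ["A", "B"])
        path = tmp_path / "m.csv"
        write_matrix_csv(matrix, path)
        back = read_matrix_csv(path)
        assert back.node_names == matrix.node_names
        assert np.array_equal(back.counts, matrix.counts)

    def test_connectivity_matrix_frame_symmetric(self):
        scheme = make_scheme({"A": ["x"], "B": ["y"]})
        net = connectivity_network(
            cooccurrence_counts(make_tags({"A", "B"}), ["A", "B"]), scheme
        )
        frame = connectivity_matrix_frame(net)
        assert frame.loc["A", "B"] == frame.loc["B", "A"] == pytest.approx(0.5)
        assert frame.loc["A", "A"] == 0.0
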