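"""Traffic-network construction, centralities, and stream connectivity."""

import itertools

import networkx as nx
import numpy as np
import pandas as pd
import pytest

from aisrisk.errors import EmptyInputError, ReferentialIntegrityError
from aisrisk.networks import (
    assign_streams,
    betweenness_centrality,
    build_traffic_network,
    connectivity_to_invaded,
    degree_centrality,
    eigenvector_centrality,
    select_centrality,
)
from aisrisk.synthetic import StreamSegment


def records(*rows):
    return pd.DataFrame(rows, columns=["station_id", "prev_id", "next_id", "eligible"])


class TestBuildNetwork:
    def test_completed_survey_yields_two_edges(self):
        g = build_traffic_network(records(("B", "A", "C", True)))
        assert set(map(frozenset, g.edges)) == {frozenset("AB"), frozenset("BC")}
        assert g.number_of_edges() == 2

    def test_absent_previous_gives_single_edge(self):
        g = build_traffic_network(records(("B", "", "C", True)))
        assert list(map(sorted, g.edges)) == [["B", "C"]]

    def test_repeated_pairs_accumulate_multiplicity(self):
        g = build_traffic_network(
            records(("B", "A", "", True), ("A", "", "B", True))
        )
        assert g["A"]["B"]["weight"] == 2

    def test_ineligible_records_contribute_nothing(self):
        g = build_traffic_network(records(("B", "A", "C", False)))
        assert g.number_of_edges() == 0

    def test_self_loop_dropped(self):
        g = build_traffic_network(records(("B", "B", "C", True)))
        assert set(map(frozenset, g.edges)) == {frozenset("BC")}

    def test_unknown_waterbody_rejected(self):
        with pytest.raises(ReferentialIntegrityError):
            build_traffic_network(records(("B", "A", "C", True)), known_ids={"B", "C"})

    def test_record_order_invariance(self):
        rows = [("B", "A", "C", True), ("D", "C", "", True), ("B", "", "D", True)]
        g1 = build_traffic_network(records(*rows))
        g2 = build_traffic_network(records(*reversed(rows)))
        assert nx.utils.graphs_equal(g1, g2)


def _dense_eigen_oracle(g: nx.Graph) -> dict:
    """Dominant eigenvector of the largest component via dense eigh."""
    comp = max(nx.connected_components(g), key=len)
    nodes = sorted(comp)
    a = nx.to_numpy_array(g, nodelist=nodes, weight="weight")
    w, v = np.linalg.eigh(a)
    vec = np.abs(v[:, np.argmax(w)])
    vec /= np.linalg.norm(vec)
    scores = {n: 0.0 for n in g.nodes}
    scores.update(dict(zip(nodes, vec)))
    return scores


class TestEigenvector:
    def test_complete_graph_symmetry(self):
        g = nx.complete_graph(4)
        cv = eigenvector_centrality(g)
        assert all(s == pytest.approx(0.5, abs=1e-9) for s in cv.scores.values())

    def test_star_hub_leaf_ratio_sqrt3(self):
        g = nx.star_graph(3)
        cv = eigenvector_centrality(g)
        assert cv.scores[0] / cv.scores[1] == pytest.approx(np.sqrt(3), abs=1e-8)

    def test_path_centre_end_ratio_sqrt2(self):
        g = nx.path_graph(["A", "B", "C"])
        cv = eigenvector_centrality(g)
        assert cv.scores["B"] / cv.scores["A"] == pytest.approx(np.sqrt(2), abs=1e-8)

    @pytest.mark.parametrize("seed", range(8))
    def test_matches_dense_eigendecomposition_on_small_graphs(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(3, 9))
        g = nx.gnp_random_graph(n, 0.5, seed=seed)
        for u, v in g.edges:
            g[u][v]["weight"] = int(rng.integers(1, 5))
        if g.number_of_edges() == 0:
            g.add_edge(0, 1, weight=1)
        cv = eigenvector_centrality(g)
        oracle = _dense_eigen_oracle(g)
        for node in g.nodes:
            assert cv.scores[node] == pytest.approx(oracle[node], abs=1e-8)

    def test_unit_norm_and_zeros_off_component(self):
        g = nx.Graph([("A", "B"), ("C", "D"), ("D", "E")])
        nx.set_edge_attributes(g, 1, "weight")
        cv = eigenvector_centrality(g)
        assert cv.scores["A"] == 0.0 and cv.scores["B"] == 0.0
        norm = np.linalg.norm(list(cv.scores.values()))
        assert norm == pytest.approx(1.0, abs=1e-10)

    def test_empty_network_rejected(self):
        with pytest.raises(EmptyInputError):
            eigenvector_centrality(nx.Graph())


def _brute_betweenness(g: nx.Graph) -> dict:
    """Exhaustive shortest-path enumeration over all unordered pairs."""
    scores = {n: 0.0 for n in g.nodes}
    for s, t in itertools.combinations(sorted(g.nodes), 2):
        try:
            paths = list(nx.all_shortest_paths(g, s, t))
        except nx.NetworkXNoPath:
            continue
        for p in paths:
            for inner in p[1:-1]:
                scores[inner] += 1.0 / len(paths)
    return scores


class TestBetweennessDegree:
    def test_path_graph_values(self):
        g = nx.path_graph(["A", "B", "C"])
        nx.set_edge_attributes(g, 1, "weight")
        bc = betweenness_centrality(g)
        assert bc.scores == {"A": 0.0, "B": 1.0, "C": 0.0}
        dc = degree_centrality(g)
        assert dc.scores == {"A": 1.0, "B": 2.0, "C": 1.0}

    def test_complete_graph_betweenness_zero(self):
        g = nx.complete_graph(5)
        assert set(betweenness_centrality(g).scores.values()) == {0.0}

    @pytest.mark.parametrize("seed", range(6))
    def test_matches_exhaustive_enumeration(self, seed):
        g = nx.gnp_random_graph(int(np.random.default_rng(seed).integers(4, 9)), 0.4, seed=seed)
        bc = betweenness_centrality(g)
        oracle = _brute_betweenness(g)
        for n in g.nodes:
            assert bc.scores[n] == pytest.approx(oracle[n], abs=1e-10)


class TestSelectCentrality:
    def _status(self, values):
        return pd.Series(values, index=[f"W{i}" for i in range(len(values))], dtype=float)

    def test_highest_mean_correlation_wins(self):
        from aisrisk.networks import CentralityVector

        ids = [f"W{i}" for i in range(6)]
        status = self._status([1, 1, 0, 0, 0, 0])
        cents = {
            "eigenvector": CentralityVector("eigenvector", dict(zip(ids, [0, 0, 1, 0, 1, 0]))),
            "betweenness": CentralityVector("betweenness", dict(zip(ids, [5, 4, 0, 1, 0, 0]))),
            "degree": CentralityVector("degree", dict(zip(ids, [0, 1, 1, 1, 0, 1]))),
        }
        chosen = select_centrality(cents, {"zm": status, "ewm": status})
        assert chosen == "betweenness"

    def test_tie_breaks_to_eigenvector(self):
        from aisrisk.networks import CentralityVector

        ids = [f"W{i}" for i in range(4)]
        same = dict(zip(ids, [3.0, 2.0, 1.0, 0.0]))
        cents = {m: CentralityVector(m, dict(same)) for m in ("eigenvector", "betweenness", "degree")}
        chosen = select_centrality(cents, {"zm": self._status([1, 1, 0, 0])})
        assert chosen == "eigenvector"

    def test_agrees_with_textbook_pearson(self):
        from aisrisk.networks import CentralityVector

        rng = np.random.default_rng(42)
        ids = [f"W{i}" for i in range(30)]
        status = self._status(rng.integers(0, 2, 30))
        cents = {}
        hand = {}
        for m in ("eigenvector", "betweenness", "degree"):
            v = rng.random(30)
            cents[m] = CentralityVector(m, dict(zip(ids, v)))
            x, y = v, status.to_numpy()
            hand[m] = (
                ((x - x.mean()) * (y - y.mean())).sum()
                / np.sqrt(((x - x.mean()) ** 2).sum() * ((y - y.mean()) ** 2).sum())
            )
        assert select_centrality(cents, {"zm": status}) == max(hand, key=hand.get)

    def test_zero_variance_measure_skipped_with_warning(self):
        from aisrisk.networks import CentralityVector

        ids = [f"W{i}" for i in range(4)]
        cents = {
            "eigenvector": CentralityVector("eigenvector", {i: 1.0 for i in ids}),
            "degree": CentralityVector("degree", dict(zip(ids, [1.0, 2, 3, 4]))),
        }
        with pytest.warns(UserWarning):
            chosen = select_centrality(cents, {"zm": self._status([1, 0, 1, 0])})
        assert chosen == "degree"


def wb_frame(points):
    return pd.DataFrame(
        [(f"W{i}", x, y) for i, (x, y) in enumerate(points)], columns=["id", "x", "y"]
    )


class TestAssignStreams:
    stream = StreamSegment("H026", np.array([[0.0, 0.0], [1.0, 0.0]]))
    far_stream = StreamSegment("H031", np.array([[0.0, 5.0], [1.0, 5.0]]))

    def test_point_on_stream_gets_its_kittle(self):
        wb = wb_frame([(0.5, 0.0)])
        assert assign_streams(wb, [self.stream, self.far_stream])["W0"] == {"H026"}

    def test_invaded_point_within_buffer_gets_nearest_stream(self):
        wb = wb_frame([(0.5, 0.09)])
        out = assign_streams(wb, [self.stream], invaded_ids={"W0"})
        assert out["W0"] == {"H026"}

    def test_uninvaded_point_off_stream_gets_nothing(self):
        wb = wb_frame([(0.5, 0.09)])
        assert assign_streams(wb, [self.stream])["W0"] == set()

    def test_beyond_buffer_nothing_even_if_invaded(self):
        wb = wb_frame([(0.5, 0.15)])
        assert assign_streams(wb, [self.stream], invaded_ids={"W0"})["W0"] == set()


class TestConnectivity:
    def test_worked_kittle_example(self):
        assignments = {"A": {"H026"}, "B": {"H026"}, "C": {"H031"}}
        flags = connectivity_to_invaded(assignments, {"A"})
        assert flags == {"A": 1, "B": 1, "C": 0}

    def test_no_invasions_all_zero(self):
        assignments = {"A": {"H1"}, "B": {"H2"}}
        assert set(connectivity_to_invaded(assignments, set()).values()) == {0}

    def test_matches_pairwise_shared_id_scan(self):
        rng = np.random.default_rng(17)
        ids = [f"W{i}" for i in range(50)]
        assignments = {
            w: set(rng.choice([f"H{k}" for k in range(8)], rng.integers(0, 3), replace=False))
            for w in ids
        }
        invaded = set(rng.choice(ids, 6, replace=False))
        flags = connectivity_to_invaded(assignments, invaded)
        for w in ids:
            brute = any(
                assignments[w] & assignments[v] for v in invaded
            )
            assert flags[w] == int(brute)

    def test_symmetric_and_idempotent(self):
        assignments = {"A": {"H1"}, "B": {"H1"}, "C": set()}
        f1 = connectivity_to_invaded(assignments, {"A"})
        f2 = connectivity_to_invaded(assignments, {"B"})
        assert f1["B"] == f2["A"] == 1  # sharing relation is symmetric
        assert connectivity_to_invaded(assignments, {"A"}) == f1
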