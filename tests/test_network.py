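"""Correlation graph construction, shortest pathways and centrality against
brute-force enumeration oracles, plus planted-path recovery."""

import itertools

import networkx as nx
import numpy as np
import pytest

from corrshuttle import (
    PlantedNetworkParams,
    Site,
    Trajectory,
    TrajectoryEnsemble,
    aromatic_hop_pathway,
    betweenness,
    build_graph,
    displacement_correlation,
    generate_planted_network_trajectory,
    shortest_pathway,
)
from corrshuttle.exceptions import NoPathError, ParameterError


# ---------------------------------------------------------------------------
# enumeration oracles
# ---------------------------------------------------------------------------


def enumerate_shortest(G, source, sink):
    """All minimum-weight simple paths by exhaustive enumeration."""
    best, paths = np.inf, []
    for path in nx.all_simple_paths(G, source, sink):
        w = sum(G[a][b]["weight"] for a, b in zip(path[:-1], path[1:]))
        if w < best - 1e-12:
            best, paths = w, [path]
        elif abs(w - best) <= 1e-12:
            paths.append(path)
    return best, paths


def enumerate_betweenness(G):
    """Weighted betweenness by enumerating all shortest paths for all pairs."""
    nodes = sorted(G.nodes())
    n = len(nodes)
    score = dict.fromkeys(nodes, 0.0)
    for s, t in itertools.combinations(nodes, 2):
        try:
            _w, paths = enumerate_shortest(G, s, t)
        except nx.NetworkXNoPath:
            continue
        if not paths:
            continue
        for path in paths:
            for v in path[1:-1]:
                score[v] += 1.0 / len(paths)
    norm = 2.0 / ((n - 1) * (n - 2)) if n > 2 else 1.0
    return {v: score[v] * norm for v in nodes}


def _ensemble_from_displacements(disp, rest=None):
    n_frames, n_beads, _ = disp.shape
    if rest is None:
        rest = np.zeros((n_beads, 3))
        rest[:, 0] = 0.4 * np.arange(n_beads)
    topo = [Site("CA", i + 1, "ALA", "NET") for i in range(n_beads)]
    return TrajectoryEnsemble(topo, [Trajectory(rest[None] + disp, 0.1)])


class TestCorrelationMatrix:
    def test_lockstep_beads_fully_correlated(self, rng):
        x = rng.normal(0, 0.05, (2000, 1, 3))
        disp = np.concatenate([x, x, rng.normal(0, 0.05, (2000, 1, 3))], axis=1)
        C = displacement_correlation(_ensemble_from_displacements(disp)).matrix
        assert C[0, 1] == pytest.approx(1.0)

    def test_equal_and_opposite_beads_anticorrelated(self, rng):
        x = rng.normal(0, 0.05, (2000, 1, 3))
        disp = np.concatenate([x, -x], axis=1)
        C = displacement_correlation(_ensemble_from_displacements(disp)).matrix
        assert C[0, 1] == pytest.approx(-1.0)

    def test_symmetric_unit_diagonal(self, rng):
        disp = rng.normal(0, 0.05, (500, 6, 3))
        C = displacement_correlation(_ensemble_from_displacements(disp)).matrix
        np.testing.assert_allclose(C, C.T, atol=1e-12)
        np.testing.assert_allclose(np.diag(C), 1.0)

    def test_zero_variance_bead_flagged(self, rng):
        disp = rng.normal(0, 0.05, (500, 4, 3))
        disp[:, 2, :] = 0.0
        res = displacement_correlation(_ensemble_from_displacements(disp))
        assert "NET:3" in res.zero_variance
        assert np.all(res.matrix[2, [0, 1, 3]] == 0.0)

    def test_planted_trajectory_matches_requested_matrix(self):
        sample = generate_planted_network_trajectory(
            PlantedNetworkParams(n_frames=50_000, seed=40)
        )
        res = displacement_correlation(sample.ensemble)
        assert np.abs(res.matrix - sample.correlation).max() < 0.03


class TestBuildGraph:
    def test_ring_contact_adjacency(self):
        sample = generate_planted_network_trajectory(PlantedNetworkParams(n_frames=200, seed=1))
        G = build_graph(displacement_correlation(sample.ensemble), sample.ensemble,
                        contact_cutoff=0.5, occupancy=0.75)
        assert G.number_of_nodes() == 24
        degs = dict(G.degree())
        assert all(d == 2 for d in degs.values())  # pure ring

    def test_edge_weight_formula(self, rng):
        x = rng.normal(0, 0.05, (5000, 1, 3))
        e = rng.normal(0, 0.05, (5000, 1, 3))
        disp = np.concatenate([x, x, e], axis=1)  # |C01|=1 -> weight 0
        ens = _ensemble_from_displacements(disp)
        G = build_graph(displacement_correlation(ens), ens, contact_cutoff=0.6, occupancy=0.5)
        assert G["NET:1"]["NET:2"]["weight"] == pytest.approx(0.0, abs=1e-9)
        w = G["NET:2"]["NET:3"]["weight"]
        assert w == pytest.approx(-np.log(abs(G["NET:2"]["NET:3"]["correlation"])))

    def test_transient_contact_filtered_by_occupancy(self, rng):
        n = 1000
        rest = np.zeros((2, 3))
        coords = np.repeat(rest[None], n, axis=0)
        coords[: n // 2, 1, 0] = 0.3   # within cutoff half the time
        coords[n // 2 :, 1, 0] = 2.0   # far otherwise
        coords += rng.normal(0, 0.01, coords.shape)
        topo = [Site("CA", i + 1, "ALA", "NET") for i in range(2)]
        ens = TrajectoryEnsemble(topo, [Trajectory(coords, 0.1)])
        G = build_graph(displacement_correlation(ens), ens, contact_cutoff=0.5, occupancy=0.75)
        assert G.number_of_edges() == 0

    def test_invalid_parameters_rejected(self):
        sample = generate_planted_network_trajectory(PlantedNetworkParams(n_frames=50, seed=1))
        corr = displacement_correlation(sample.ensemble)
        with pytest.raises(ParameterError):
            build_graph(corr, sample.ensemble, contact_cutoff=-1.0)
        with pytest.raises(ParameterError):
            build_graph(corr, sample.ensemble, occupancy=1.5)


class TestShortestPathway:
    def test_two_node_single_edge(self):
        G = nx.Graph()
        G.add_edge("a", "b", weight=0.3)
        res = shortest_pathway(G, "a", "b")
        assert res.nodes == ("a", "b")
        assert res.total_weight == pytest.approx(0.3)

    def test_matches_enumeration_on_random_six_node_graphs(self, rng):
        for trial in range(20):
            G = nx.gnp_random_graph(6, 0.6, seed=int(rng.integers(1e6)))
            if not nx.has_path(G, 0, 5):
                continue
            H = nx.Graph()
            for a, b in G.edges():
                H.add_edge(f"n{a}", f"n{b}", weight=float(rng.uniform(0.1, 2.0)))
            if not nx.has_path(H, "n0", "n5"):
                continue
            res = shortest_pathway(H, "n0", "n5")
            best, paths = enumerate_shortest(H, "n0", "n5")
            assert res.total_weight == pytest.approx(best, abs=1e-9)
            assert list(res.nodes) in [list(p) for p in paths]

    def test_tie_broken_lexicographically(self):
        G = nx.Graph()
        # two equal-weight routes a-b-z and a-c-z
        G.add_edge("a", "b", weight=1.0)
        G.add_edge("b", "z", weight=1.0)
        G.add_edge("a", "c", weight=1.0)
        G.add_edge("c", "z", weight=1.0)
        assert shortest_pathway(G, "a", "z").nodes == ("a", "b", "z")

    def test_disconnected_endpoints_raise_with_components(self):
        G = nx.Graph()
        G.add_edge("a", "b", weight=1.0)
        G.add_edge("x", "y", weight=1.0)
        with pytest.raises(NoPathError, match="disconnected"):
            shortest_pathway(G, "a", "x")

    def test_planted_path_recovered_across_seeds(self):
        hits = 0
        n_seeds = 5
        for seed in range(n_seeds):
            sample = generate_planted_network_trajectory(
                PlantedNetworkParams(n_frames=10_000, seed=1000 + seed)
            )
            G = build_graph(displacement_correlation(sample.ensemble), sample.ensemble)
            res = shortest_pathway(G, sample.path_labels[0], sample.path_labels[-1])
            hits += res.nodes == sample.path_labels
        assert hits == n_seeds

    def test_two_bead_planted_path_trivially_recovered(self):
        sample = generate_planted_network_trajectory(
            PlantedNetworkParams(planted_path=(3, 4), n_frames=5000, seed=7)
        )
        G = build_graph(displacement_correlation(sample.ensemble), sample.ensemble)
        res = shortest_pathway(G, "NET:4", "NET:5")
        assert res.nodes == ("NET:4", "NET:5")


class TestBetweenness:
    def test_path_graph_interior_maximal(self):
        G = nx.path_graph([f"n{i}" for i in range(5)])
        nx.set_edge_attributes(G, 1.0, "weight")
        bc = betweenness(G)
        assert max(bc, key=bc.get) == "n2"
        assert bc["n0"] == 0.0

    def test_star_graph_hub_is_one(self):
        G = nx.Graph()
        for leaf in "abcd":
            G.add_edge("hub", leaf, weight=1.0)
        bc = betweenness(G)
        assert bc["hub"] == pytest.approx(1.0)
        assert bc["a"] == 0.0

    def test_matches_enumeration_on_random_eight_node_graphs(self, rng):
        for trial in range(5):
            G0 = nx.gnp_random_graph(8, 0.5, seed=int(rng.integers(1e6)))
            G = nx.Graph()
            for a, b in G0.edges():
                G.add_edge(f"n{a}", f"n{b}", weight=float(rng.uniform(0.2, 2.0)))
            if G.number_of_nodes() < 3:
                continue
            bc = betweenness(G)
            oracle = enumerate_betweenness(G)
            for v in G.nodes():
                assert bc[v] == pytest.approx(oracle[v], abs=1e-9)


class TestAromaticHop:
    def _frame_ensemble(self, positions, resnames):
        topo = [Site("CA", i + 1, rn, "NET") for i, rn in enumerate(resnames)]
        coords = np.asarray(positions, dtype=float)[None]
        return TrajectoryEnsemble(topo, [Trajectory(coords, 0.1)])

    def test_collinear_aromatic_chain_visits_all(self):
        pos = [[0, 0, 0], [0.6, 0, 0], [1.2, 0, 0]]
        ens = self._frame_ensemble(pos, ["TRP", "TYR", "PHE"])
        res = aromatic_hop_pathway(ens, "NET:1", "NET:3", hop_cutoff=0.8)
        assert res.nodes == ("NET:1", "NET:2", "NET:3")

    def test_cutoff_below_spacing_raises(self):
        pos = [[0, 0, 0], [0.6, 0, 0], [1.2, 0, 0]]
        ens = self._frame_ensemble(pos, ["TRP", "TYR", "PHE"])
        with pytest.raises(NoPathError, match="hop_cutoff"):
            aromatic_hop_pathway(ens, "NET:1", "NET:3", hop_cutoff=0.5)

    def test_shorter_total_route_chosen(self):
        # direct 1->3 hop (0.75) beats 1->2->3 (0.4 + 0.4)
        pos = [[0, 0, 0], [0.375, 0.14, 0], [0.75, 0, 0]]
        ens = self._frame_ensemble(pos, ["TRP", "TYR", "PHE"])
        res = aromatic_hop_pathway(ens, "NET:1", "NET:3", hop_cutoff=0.8)
        G = nx.Graph()
        labels = ["NET:1", "NET:2", "NET:3"]
        for i in range(3):
            for j in range(i + 1, 3):
                d = float(np.linalg.norm(np.array(pos[i]) - np.array(pos[j])))
                if d < 0.8:
                    G.add_edge(labels[i], labels[j], weight=d)
        best, paths = enumerate_shortest(G, "NET:1", "NET:3")
        assert res.total_weight == pytest.approx(best, abs=1e-12)
        assert res.nodes == ("NET:1", "NET:3")
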