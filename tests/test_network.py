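"""Correlation matrices, information distances and communication paths."""

import math

import networkx as nx
import numpy as np
import pytest

import allopath as ap
from allopath.network import (
    InformationDistanceMatrix,
    NetworkAnalysisError,
    _lexicographic_shortest_path,
)

from conftest import brute_force_minimal_path, recoverable_spec, single_residue_traj


class TestCorrelationMatrix:
    def test_identical_fluctuations_corr_one(self):
        rng = np.random.default_rng(0)
        f = rng.normal(size=(200, 1, 3))
        ca = np.concatenate([f, f, rng.normal(size=(200, 1, 3))], axis=1)
        corr = ap.correlation_matrix(ca, align=False)
        assert corr.values[0, 1] == pytest.approx(1.0, abs=1e-12)

    def test_anticorrelated_fluctuations_corr_minus_one(self):
        rng = np.random.default_rng(1)
        f = rng.normal(size=(200, 1, 3))
        ca = np.concatenate([f, -f, rng.normal(size=(200, 1, 3))], axis=1)
        corr = ap.correlation_matrix(ca, align=False)
        assert corr.values[0, 1] == pytest.approx(-1.0, abs=1e-12)

    def test_planted_neighbour_correlation_across_seeds(self):
        # lambda=1, noise 0.5 Å, 1000 frames: closed form 0.8 within 0.05
        vals = []
        for seed in range(20):
            spec = ap.PlantedNetworkSpec(
                n_residues=8, planted_path=(0, 1, 2), loading=1.0, noise_sd=0.5,
                n_frames=1000, seed=seed,
            )
            traj = ap.make_planted_network_traj(spec)
            corr = ap.correlation_matrix(traj, align=False)
            vals.append(corr.values[0, 1])
        assert np.mean(vals) == pytest.approx(0.8, abs=0.05)

    def test_diagonal_and_symmetry(self):
        traj = ap.make_planted_network_traj(recoverable_spec(seed=4, n_frames=100))
        corr = ap.correlation_matrix(traj, align=True)
        assert np.allclose(np.diag(corr.values), 1.0)
        assert np.allclose(corr.values, corr.values.T, atol=1e-12)
        assert corr.values.max() <= 1.0 and corr.values.min() >= -1.0

    def test_frozen_residue_flagged_as_zero(self):
        rng = np.random.default_rng(2)
        ca = rng.normal(size=(50, 3, 3))
        ca[:, 1, :] = 7.0  # frozen residue
        corr = ap.correlation_matrix(ca, align=False)
        assert np.all(corr.values[1, [0, 2]] == 0.0)
        assert corr.values[1, 1] == 1.0


class TestInformationDistance:
    def test_edge_rule_pin(self):
        # G_cut = 0.40 keeps pairs with |Corr| > 0.67 only under natural log
        assert math.exp(-0.40) == pytest.approx(0.67, abs=0.005)
        corr = ap.correlation_matrix(
            np.random.default_rng(0).normal(size=(30, 3, 3)), align=False
        )
        vals = corr.values.copy()
        vals[0, 1] = vals[1, 0] = 0.67
        corr2 = ap.CorrelationMatrix(vals, corr.residues, 30, False)
        d = ap.information_distance(corr2)
        assert d.values[0, 1] == pytest.approx(0.400, abs=5e-4)

    def test_known_values(self):
        vals = np.array([[1.0, math.exp(-1)], [math.exp(-1), 1.0]])
        corr = ap.CorrelationMatrix(vals, (("A", 1), ("A", 2)), 10, False)
        d = ap.information_distance(corr)
        assert d.values[0, 0] == 0.0  # |Corr| = 1 on the diagonal
        assert d.values[0, 1] == pytest.approx(1.0, abs=1e-12)

    def test_zero_correlation_gives_infinite_distance(self):
        vals = np.eye(2)
        corr = ap.CorrelationMatrix(vals, (("A", 1), ("A", 2)), 10, False)
        d = ap.information_distance(corr)
        assert np.isinf(d.values[0, 1])


def _random_distance_matrix(seed, n=30):
    rng = np.random.default_rng(seed)
    c = rng.uniform(-1, 1, size=(n, n))
    c = (c + c.T) / 2
    np.fill_diagonal(c, 1.0)
    with np.errstate(divide="ignore"):
        d = -np.log(np.abs(c))
    d[np.abs(c) == 0] = np.inf
    np.fill_diagonal(d, 0.0)
    keys = tuple(("A", i + 1) for i in range(n))
    return InformationDistanceMatrix(values=d, residues=keys), d


class TestBuildGraph:
    def test_edges_match_brute_force_threshold(self):
        dist, d = _random_distance_matrix(3)
        g = ap.build_graph(dist, g_cut=0.40)
        expect = {
            (("A", i + 1), ("A", j + 1))
            for i in range(30)
            for j in range(i + 1, 30)
            if d[i, j] < 0.40
        }
        assert {tuple(sorted(e)) for e in g.edges} == expect

    def test_example_correlations(self):
        # |Corr| = 0.70 -> d = 0.357 (edge); |Corr| = 0.60 -> d = 0.511 (no edge)
        vals = np.array([[1.0, 0.70, 0.60], [0.70, 1.0, 0.1], [0.60, 0.1, 1.0]])
        corr = ap.CorrelationMatrix(vals, (("A", 1), ("A", 2), ("A", 3)), 10, False)
        g = ap.build_graph(ap.information_distance(corr), g_cut=0.40)
        assert g.has_edge(("A", 1), ("A", 2))
        assert not g.has_edge(("A", 1), ("A", 3))

    def test_invalid_gcut_rejected(self):
        dist, _ = _random_distance_matrix(0)
        with pytest.raises(NetworkAnalysisError):
            ap.build_graph(dist, g_cut=0.0)


class TestDefineRegion:
    def test_static_membership_and_boundary(self):
        positions = {
            ("A", 1): [0.0, 0.0, 0.0],     # centre
            ("A", 2): [6.9, 0.0, 0.0],     # inside 7 Å
            ("A", 3): [7.1, 0.0, 0.0],     # outside
        }
        traj = single_residue_traj(positions, n_frames=10)
        region = ap.define_region(traj, [("A", 1)], radius=7.0, occupancy=0.70)
        assert ("A", 2) in region.members
        assert ("A", 3) not in region.members
        assert ("A", 1) in region.members

    def test_occupancy_boundary_excluded(self):
        # inside the sphere in 69 of 100 frames -> below the 70% rule
        traj = single_residue_traj({("A", 1): [0, 0, 0], ("A", 2): [6, 0, 0]}, n_frames=100)
        coords = traj.coords.copy()
        coords[69:, 3, 0] = 50.0  # CA of residue 2 leaves after frame 68
        coords[69:, 2, 0] = 50.0
        traj2 = ap.TrajectoryEnsemble(atoms=traj.atoms, coords=coords)
        region = ap.define_region(traj2, [("A", 1)], radius=7.0, occupancy=0.70)
        assert ("A", 2) not in region.members

    def test_membership_matches_brute_force(self):
        rng = np.random.default_rng(7)
        positions = {("A", i): rng.uniform(0, 25, 3) for i in range(1, 26)}
        traj = single_residue_traj(positions, n_frames=3)
        region = ap.define_region(traj, [("A", 1), ("A", 13)], radius=7.0)
        expect = {
            k
            for k, p in positions.items()
            if min(
                np.linalg.norm(np.array(p) - positions[("A", 1)]),
                np.linalg.norm(np.array(p) - positions[("A", 13)]),
            )
            < 7.0
        } | {("A", 1), ("A", 13)}
        assert set(region.members) == expect

    def test_unknown_center_rejected(self):
        traj = single_residue_traj({("A", 1): [0, 0, 0]}, n_frames=2)
        with pytest.raises(NetworkAnalysisError):
            ap.define_region(traj, [("B", 9)])


def _region(*keys, label="r"):
    return ap.Region(label=label, center_residues=(keys[0],), members=tuple(keys))


class TestShortestPaths:
    def test_hand_graph_matches_enumeration(self):
        g = nx.Graph()
        edges = [
            ("a", "b", 0.1), ("b", "c", 0.2), ("a", "c", 0.35),
            ("c", "d", 0.15), ("b", "d", 0.4), ("d", "e", 0.05),
        ]
        for u, v, w in edges:
            g.add_edge(u, v, weight=w)
        report = ap.shortest_paths(
            g, _region("a", label="s"), _region("e", label="t")
        )
        path, length = brute_force_minimal_path(g, "a", "e")
        got_path, got_len = report.paths[("a", "e")]
        assert got_path == path
        assert got_len == pytest.approx(length, abs=1e-12)
        assert report.d_min_mean == pytest.approx(length, abs=1e-12)

    def test_single_edge_graph(self):
        g = nx.Graph()
        g.add_edge("s", "t", weight=0.3)
        report = ap.shortest_paths(g, _region("s"), _region("t"))
        assert report.d_min_mean == pytest.approx(0.3)
        assert report.ci["s"] == 1.0 and report.ci["t"] == 1.0

    def test_random_graphs_match_brute_force(self):
        # spot-check here; the full 200-graph sweep runs in the acceptance suite
        for seed in range(25):
            rng = np.random.default_rng(seed)
            n = int(rng.integers(4, 10))
            g = nx.gnp_random_graph(n, 0.5, seed=int(seed))
            for u, v in g.edges:
                g[u][v]["weight"] = float(np.round(rng.uniform(0.05, 0.4), 6))
            if 0 not in g or n - 1 not in g:
                continue
            got = _lexicographic_shortest_path(g, 0, n - 1)
            expect = brute_force_minimal_path(g, 0, n - 1)
            if expect is None:
                assert got is None
            else:
                assert got is not None
                assert got[1] == pytest.approx(expect[1], abs=1e-9)
                assert got[0] == expect[0]

    def test_no_reachable_pair_reports_no_path(self):
        g = nx.Graph()
        g.add_nodes_from(["s", "t"])
        report = ap.shortest_paths(g, _region("s"), _region("t"))
        assert report.no_path
        assert report.d_min_mean is None
        assert report.n_unreachable == 1

    def test_overlapping_regions_rejected(self):
        g = nx.Graph()
        g.add_edge("s", "t", weight=0.1)
        with pytest.raises(NetworkAnalysisError):
            ap.shortest_paths(g, _region("s", "t"), _region("t"))

    def test_planted_chain_recovered(self):
        spec = recoverable_spec(seed=0)
        traj = ap.make_planted_network_traj(spec)
        corr = ap.correlation_matrix(traj, align=False)
        graph = ap.build_graph(ap.information_distance(corr), g_cut=0.40)
        report = ap.shortest_paths(
            graph, _region(("A", 1), label="s"), _region(("A", 5), label="t")
        )
        path, _ = report.paths[(("A", 1), ("A", 5))]
        assert path == [("A", 1), ("A", 2), ("A", 3), ("A", 4), ("A", 5)]
        for r in path:
            assert report.ci[r] == 1.0

    def test_ci_on_every_reported_path_is_one(self):
        g = nx.Graph()
        for u, v, w in [("s", "m", 0.1), ("m", "t", 0.1), ("s", "x", 0.3), ("x", "t", 0.3)]:
            g.add_edge(u, v, weight=w)
        report = ap.shortest_paths(g, _region("s"), _region("t"))
        for node in report.paths[("s", "t")][0]:
            assert report.ci[node] == 1.0


class TestGcutScan:
    def test_monotone_edge_counts_and_limits(self):
        dist, d = _random_distance_matrix(11, n=20)
        finite = np.isfinite(d) & (d > 0)
        src = _region(("A", 1), label="s")
        snk = _region(("A", 20), label="t")
        lo = d[finite].min() / 2
        hi = d[finite].max() * 1.01
        rows = ap.gcut_scan(dist, src, snk, sorted([lo, 0.2, 0.4, 1.0, hi]))
        counts = [r["n_edges"] for r in rows]
        assert counts == sorted(counts)
        assert counts[0] == 0
        assert counts[-1] == np.count_nonzero(np.triu(finite, k=1))

    def test_path_lengths_non_increasing_in_gcut(self):
        dist, _ = _random_distance_matrix(13, n=15)
        src = _region(("A", 1), label="s")
        snk = _region(("A", 15), label="t")
        rows = ap.gcut_scan(dist, src, snk, [0.3, 0.6, 1.2, 2.4])
        lengths = [r["d_min_mean"] for r in rows if r["d_min_mean"] is not None]
        assert all(a >= b - 1e-12 for a, b in zip(lengths, lengths[1:]))

    def test_unsorted_g_values_rejected(self):
        dist, _ = _random_distance_matrix(0, n=5)
        with pytest.raises(NetworkAnalysisError):
            ap.gcut_scan(dist, _region(("A", 1)), _region(("A", 5)), [0.4, 0.2])
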