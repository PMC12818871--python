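"""Directed simplices, enrichment, hex binning, and meso-scale graphs."""

import itertools
import math

import numpy as np
import pytest

from cortexkit.network import SpikeRecording
from cortexkit.topology import (MesoGraph, correlation_vs_distance, hex_bin,
                                hypergeom_enrichment, input_correlation_estimate,
                                meso_graph, midrange_local_ratio,
                                missing_synapses, node_participation, rich_club,
                                simplex_counts, top_participation_set,
                                weighted_mean_by_dimension)


def brute_force_participation(edges, n_nodes):
    """Independent oracle via subset dynamic programming.

    A directed simplex is an ordered tuple where every earlier node sends an
    edge to every later node; each feed-forward ordering is a distinct
    simplex (so a reciprocal edge pair contributes two 1-simplices, making
    Par_1 the total degree). w(S) counts valid orderings of exactly the node
    set S: w(S) = sum over v in S with S \\ {v} fully presynaptic to v of
    w(S \\ {v}). Participation sums w(S) over the subsets containing a node.
    """
    pred = [0] * n_nodes
    for u, v in set(edges):
        pred[v] |= 1 << u
    w = np.zeros(1 << n_nodes, dtype=np.int64)
    w[0] = 1
    for S in range(1, 1 << n_nodes):
        total = 0
        rest = S
        while rest:
            v = (rest & -rest).bit_length() - 1
            rest &= rest - 1
            others = S & ~(1 << v)
            if others & ~pred[v] == 0:  # all other members project to v
                total += w[others]
        w[S] = total
    par = np.zeros((n_nodes, n_nodes), dtype=np.int64)
    par[:, 0] = 1
    for S in range(1, 1 << n_nodes):
        k = bin(S).count("1") - 1
        if k >= 1 and w[S] > 0:
            for v in range(n_nodes):
                if S >> v & 1:
                    par[v, k] += w[S]
    return par


class TestNodeParticipation:
    def test_edgeless_graph_zero(self):
        par = node_participation([], n_nodes=5, max_dim=3)
        assert np.all(par[:, 1:] == 0)
        assert np.all(par[:, 0] == 1)

    def test_total_degree_in_dimension_one(self):
        edges = [(0, 1), (1, 2), (2, 0), (0, 2)]
        par = node_participation(edges, n_nodes=3)
        degrees = {0: 3, 1: 2, 2: 3}   # in + out
        for v, d in degrees.items():
            assert par[v, 1] == d

    def test_complete_feedforward_four_nodes(self):
        """Total order on 4 nodes: Par_1 = 3 and Par_3 = 1 for every node."""
        edges = [(i, j) for i in range(4) for j in range(i + 1, 4)]
        par = node_participation(edges, n_nodes=4)
        assert np.all(par[:, 1] == 3)
        assert np.all(par[:, 3] == 1)
        assert simplex_counts(edges, n_nodes=4)[3] == 1

    @pytest.mark.parametrize("k", [3, 5, 7])
    def test_complete_feedforward_binomial_closed_form(self, k):
        """On the complete feed-forward digraph, Par_d(v) = C(k-1, d)."""
        edges = [(i, j) for i in range(k) for j in range(i + 1, k)]
        par = node_participation(edges, n_nodes=k)
        for d in range(1, k):
            assert np.all(par[:, d] == math.comb(k - 1, d))

    def test_matches_brute_force_on_er_graphs(self):
        """200 random ER digraphs with <= 12 nodes, all dimensions."""
        rng = np.random.default_rng(0)
        for trial in range(200):
            n = int(rng.integers(3, 13))
            p = rng.uniform(0.1, 0.5)
            edges = [(i, j) for i in range(n) for j in range(n)
                     if i != j and rng.random() < p]
            par = node_participation(edges, n_nodes=n)
            oracle = brute_force_participation(edges, n)
            assert np.array_equal(par[:, :oracle.shape[1]], oracle), \
                f"mismatch on trial {trial}"

    def test_self_loop_rejected(self):
        with pytest.raises(ValueError):
            node_participation([(0, 0)], n_nodes=1)

    def test_invalid_max_dim_rejected(self):
        with pytest.raises(ValueError):
            node_participation([(0, 1)], max_dim=0)


class TestWeightedMean:
    def test_constant_values_identity(self):
        edges = [(i, j) for i in range(4) for j in range(i + 1, 4)]
        par = node_participation(edges, n_nodes=4)
        for k in range(1, 4):
            assert weighted_mean_by_dimension(np.full(4, 2.5), par, k) == \
                pytest.approx(2.5)

    def test_concentrated_participation(self):
        par = np.zeros((3, 2), dtype=np.int64)
        par[1, 1] = 7
        values = np.array([1.0, 9.0, 5.0])
        assert weighted_mean_by_dimension(values, par, 1) == 9.0

    def test_hand_computed_four_node_example(self):
        edges = [(0, 1), (0, 2), (1, 2), (3, 2)]
        par = node_participation(edges, n_nodes=4)
        values = np.array([1.0, 2.0, 3.0, 4.0])
        k = 1
        expected = np.dot(values, par[:, k]) / par[:, k].sum()
        assert weighted_mean_by_dimension(values, par, k) == \
            pytest.approx(expected)
        # compatibility mode divides by the node count
        assert weighted_mean_by_dimension(values, par, k,
                                          compat_normalization=True) == \
            pytest.approx(expected / 4)

    def test_empty_dimension_rejected(self):
        par = np.zeros((3, 3), dtype=np.int64)
        with pytest.raises(ZeroDivisionError):
            weighted_mean_by_dimension(np.ones(3), par, 2)


class TestHypergeomEnrichment:
    def test_direct_combinatorics(self):
        """N=10, 5 marked, sample 2, all 2 marked: p_over = C(5,2)/C(10,2)."""
        _, p_over = hypergeom_enrichment(10, 5, 2, 2)
        assert p_over == pytest.approx(10 / 45)

    def test_full_cdf_is_one(self):
        p_under, _ = hypergeom_enrichment(10, 5, 4, 4)
        assert p_under == pytest.approx(1.0)

    def test_tail_identity_shared_mass(self):
        """p_under(C_m) + p_over(C_m) >= 1 (both tails contain C_m)."""
        for cm in range(0, 5):
            p_u, p_o = hypergeom_enrichment(20, 8, 5, cm)
            assert p_u + p_o >= 1.0 - 1e-12

    def test_top_set_includes_cutoff_ties(self):
        par = np.zeros((10, 2), dtype=np.int64)
        par[:, 1] = [9, 5, 5, 5, 1, 1, 1, 1, 1, 1]
        top = top_participation_set(par, 1, top_fraction=0.2)
        # top-2 cutoff value is 5; all three tied nodes included
        assert set(top) == {0, 1, 2, 3}


class TestHexBin:
    def test_points_at_centers_stay_put(self):
        xy = np.array([[0.0, 0.0], [520.0, 0.0], [260.0, 450.333]])
        assign, centers = hex_bin(xy, 520.0)
        assert len(np.unique(assign)) == 3
        for i in range(3):
            assert np.linalg.norm(centers[assign[i]] - xy[i]) < 1.0

    def test_small_displacement_same_hexagon(self):
        xy = np.array([[0.0, 0.0], [1.0, 0.0]])
        assign, _ = hex_bin(xy, 520.0)
        assert assign[0] == assign[1]

    def test_partition_preserves_counts(self):
        rng = np.random.default_rng(1)
        xy = rng.uniform(0, 2000, size=(500, 2))
        assign, centers = hex_bin(xy, 400.0)
        counts = np.bincount(assign, minlength=len(centers))
        assert counts.sum() == 500

    def test_adjacent_centers_at_tiling_pitch(self):
        rng = np.random.default_rng(2)
        xy = rng.uniform(0, 1000, size=(2000, 2))
        _, centers = hex_bin(xy, 200.0)
        d = np.linalg.norm(centers[:, None] - centers[None], axis=2)
        nearest = np.sort(np.unique(np.round(d[d > 0], 6)))[0]
        assert nearest == pytest.approx(200.0, rel=1e-6)


def toy_meso(S, F, centers=None, diameter=100.0):
    n = len(S)
    if centers is None:
        centers = np.column_stack([np.arange(n) * diameter, np.zeros(n)])
    return MesoGraph(centers_um=np.asarray(centers, dtype=float),
                     S=np.asarray(S), F=np.asarray(F, dtype=float),
                     hex_diameter_um=diameter,
                     assignment=np.zeros(1, dtype=int))


class TestMesoGraph:
    def make_recording(self, n_neurons, xy, duration=10_000.0, seed=0,
                       copies=False):
        rng = np.random.default_rng(seed)
        base = np.sort(rng.uniform(0, duration, 400))
        ids, times = [], []
        for i in range(n_neurons):
            t = base if copies else np.sort(rng.uniform(0, duration, 400))
            ids.append(np.full(len(t), i))
            times.append(t)
        rec = SpikeRecording(neuron_ids=np.concatenate(ids),
                             times_ms=np.concatenate(times), duration=duration,
                             pop_index=np.zeros(n_neurons, dtype=int),
                             pop_labels=["L5_E"])
        return rec

    def test_single_subvolume_total_count(self):
        xy = np.zeros((4, 2))
        rec = self.make_recording(4, xy)
        m = meso_graph(rec, xy, edge_pre=np.array([0, 1]),
                       edge_post=np.array([2, 3]), edge_nsyn=np.array([5, 7]),
                       hex_diameter_um=400.0)
        assert m.S.shape == (1, 1)
        assert m.S[0, 0] == 12

    def test_independent_activity_near_zero_correlation(self):
        xy = np.array([[0.0, 0.0], [0.0, 0.0], [800.0, 0.0], [800.0, 0.0]])
        rec = self.make_recording(4, xy, seed=3)
        m = meso_graph(rec, xy, np.array([0]), np.array([2]), np.array([1]),
                       hex_diameter_um=400.0)
        assert abs(m.F[0, 1]) < 0.1

    def test_duplicated_trains_unit_correlation(self):
        xy = np.array([[0.0, 0.0], [800.0, 0.0]])
        rec = self.make_recording(2, xy, copies=True)
        m = meso_graph(rec, xy, np.array([0]), np.array([1]), np.array([1]),
                       hex_diameter_um=400.0)
        assert m.F[0, 1] == pytest.approx(1.0)


class TestInputCorrelation:
    def test_perfectly_correlated_sources(self):
        S = np.array([[0, 0, 3], [0, 0, 5], [0, 0, 0]])
        F = np.ones((3, 3))
        _, _, mean = input_correlation_estimate(toy_meso(S, F), target=2)
        assert mean == pytest.approx(1.0)

    def test_single_source_self_correlation(self):
        S = np.array([[0, 4], [0, 0]])
        F = np.array([[0.37, 0.1], [0.1, 0.5]])
        vals, w, mean = input_correlation_estimate(toy_meso(S, F), target=1)
        assert mean == pytest.approx(0.37)  # concentrated on F[0, 0]

    def test_two_source_hand_arithmetic(self):
        """Counts (2, 1) with pair correlations {0, 0.5}: the weighted mean
        follows S_i P S_i^T arithmetic exactly."""
        S = np.array([[0, 0, 2], [0, 0, 1], [0, 0, 0]])
        F = np.array([[0.5, 0.0, 0.0],
                      [0.0, 0.5, 0.0],
                      [0.0, 0.0, 1.0]])
        _, _, mean = input_correlation_estimate(toy_meso(S, F), target=2)
        # weights: (0,0)=4, (1,1)=1, (0,1)+(1,0)=4 -> (4*0.5 + 1*0.5 + 0)/9
        assert mean == pytest.approx((4 * 0.5 + 1 * 0.5) / 9)

    def test_no_inputs_rejected(self):
        S = np.zeros((2, 2), dtype=int)
        with pytest.raises(ValueError):
            input_correlation_estimate(toy_meso(S, np.eye(2)), target=0)


class TestRichClub:
    def test_threshold_above_max_all_singletons(self):
        S = np.array([[0, 5], [3, 0]])
        res = rich_club(toy_meso(S, np.eye(2)), threshold_synapses=10)
        assert len(res.members) == 0
        assert res.components == []

    def test_zero_threshold_single_component(self):
        S = np.array([[0, 1, 0], [0, 0, 1], [0, 0, 0]])
        res = rich_club(toy_meso(S, np.eye(3)), threshold_synapses=1)
        assert len(res.components) == 1
        assert res.components[0] == {0, 1, 2}

    def test_constructed_component_structure(self):
        # 0-1 strongly coupled, 3-4 strongly coupled, 2 isolated
        S = np.zeros((5, 5), dtype=int)
        S[0, 1] = S[1, 0] = 100
        S[3, 4] = 100
        S[2, 0] = 5
        res = rich_club(toy_meso(S, np.eye(5)), threshold_synapses=50)
        assert sorted(map(sorted, res.components)) == [[0, 1], [3, 4]]
        assert set(res.members) == {0, 1, 3, 4}

    def test_membership_monotone_in_threshold(self):
        rng = np.random.default_rng(4)
        S = rng.integers(0, 100, size=(6, 6))
        meso = toy_meso(S, np.eye(6))
        sizes = [len(rich_club(meso, th).members) for th in (10, 30, 60, 90)]
        assert np.all(np.diff(sizes) <= 0)

    def test_adjacency_to_member_flags(self):
        S = np.zeros((3, 3), dtype=int)
        S[0, 1] = 100
        res = rich_club(toy_meso(S, np.eye(3), diameter=100.0),
                        threshold_synapses=50)
        # subvolume 2 sits one pitch from member 1
        assert res.adjacent_to_member[2]


class TestMissingSynapses:
    def test_printed_arithmetic(self):
        assert missing_synapses(5000.0, 2000)[0] == 3500

    def test_floor_when_existing_exceeds(self):
        count, flagged = missing_synapses(100.0, 500)
        assert count == 0 and flagged

    def test_zero_density(self):
        assert missing_synapses(5000.0, 0, density_per_um=0.0)[0] == 0

    def test_midrange_local_ratio(self):
        assert midrange_local_ratio(4075.0, 9138.0) == pytest.approx(44.59,
                                                                     abs=0.01)


class TestCorrelationVsDistance:
    def test_identical_activity_flat_at_one(self):
        n = 4
        F = np.ones((n, n))
        centers = np.column_stack([np.arange(n) * 100.0, np.zeros(n)])
        meso = toy_meso(np.zeros((n, n), dtype=int), F, centers)
        d, r = correlation_vs_distance(meso)
        assert np.allclose(r, 1.0)

    def test_independent_activity_flat_at_zero(self):
        rng = np.random.default_rng(5)
        n = 6
        F = rng.normal(0, 0.01, (n, n))
        F = (F + F.T) / 2
        centers = rng.uniform(0, 500, (n, 2))
        meso = toy_meso(np.zeros((n, n), dtype=int), F, centers)
        _, r = correlation_vs_distance(meso, n_bins=3)
        assert np.all(np.abs(r[np.isfinite(r)]) < 0.05)

    def test_adjacent_distance_is_pitch(self):
        centers = np.array([[0.0, 0.0], [200.0, 0.0], [400.0, 0.0]])
        meso = toy_meso(np.zeros((3, 3), dtype=int), np.ones((3, 3)), centers,
                        diameter=200.0)
        d, _ = correlation_vs_distance(meso)
        assert d[0] == pytest.approx(200.0)
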