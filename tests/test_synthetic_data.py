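"""Generators: neuron clouds, distance connectomes, planting, activity traces."""

import numpy as np
import pandas as pd
import pytest
import scipy.sparse as sp
from scipy.stats import chisquare

from simplicia import synthetic_data as sd
from simplicia.core_model import Connectome
from simplicia.simplices import enumerate_simplices


def empty_connectome(neurons):
    n = len(neurons)
    return Connectome(neurons, sp.csr_matrix((n, n), dtype=np.int64))


class TestMakeNeurons:
    def test_pure_inhibitory_table(self):
        t = sd.make_neurons(0, 5, seed=0)
        assert len(t) == 5 and (t["synapse_class"] == "I").all()

    def test_reproducible_under_seed(self):
        a = sd.make_neurons(50, 10, seed=42)
        b = sd.make_neurons(50, 10, seed=42)
        pd.testing.assert_frame_equal(a, b)

    def test_zero_volume_rejected(self):
        with pytest.raises(ValueError):
            sd.make_neurons(10, 0, volume=(0.0, 100.0, 100.0), seed=0)

    def test_uniform_density_per_octant(self):
        t = sd.make_neurons(10_000, 0, volume=(200.0, 200.0, 200.0), seed=1)
        octant = ((t.x > 100).astype(int) * 4 + (t.y > 100).astype(int) * 2
                  + (t.z > 100).astype(int))
        counts = np.bincount(octant, minlength=8)
        assert chisquare(counts).pvalue > 1e-3
        assert np.abs(counts / counts.mean() - 1).max() < 0.05 * 8 / 8 + 0.06


class TestDistanceConnectome:
    def test_coincident_points_with_unit_amplitude(self):
        neurons = sd.make_neurons(20, 0, seed=0)
        neurons[["x", "y", "z"]] = 0.0
        conn = sd.sample_distance_connectome(
            neurons, sd.DistanceModelParams.uniform(1.0, 50.0), seed=1)
        assert conn.n_edges == 20 * 19

    def test_zero_amplitude_gives_empty_graph(self):
        neurons = sd.make_neurons(50, 10, seed=2)
        conn = sd.sample_distance_connectome(
            neurons, sd.DistanceModelParams.uniform(0.0, 50.0), seed=3)
        assert conn.n_edges == 0

    def test_binned_probability_matches_model(self):
        neurons = sd.make_neurons(2000, 0, volume=(300.0, 300.0, 300.0), seed=4)
        a, b = 0.1, 100.0
        conn = sd.sample_distance_connectome(
            neurons, sd.DistanceModelParams.uniform(a, b), seed=5)
        xyz = conn.positions
        d = np.sqrt(((xyz[:, None] - xyz[None, :]) ** 2).sum(-1))
        adj = conn.adjacency.toarray() > 0
        off = ~np.eye(len(xyz), dtype=bool)
        for lo in (0, 50, 100, 150):
            sel = off & (d >= lo) & (d < lo + 50)
            p_emp = adj[sel].mean()
            p_mod = (a * np.exp(-d[sel] / b)).mean()
            se = np.sqrt(p_mod * (1 - p_mod) / sel.sum())
            assert abs(p_emp - p_mod) < 4 * se + 1e-4

    def test_invalid_params_rejected(self):
        with pytest.raises(ValueError):
            sd.DistanceModelParams.uniform(1.5, 50.0)
        with pytest.raises(ValueError):
            sd.DistanceModelParams.uniform(0.5, -1.0)

    def test_geometric_synapse_counts(self):
        neurons = sd.make_neurons(100, 0, seed=6)
        conn = sd.sample_distance_connectome(
            neurons, sd.DistanceModelParams.uniform(0.3, 200.0), seed=7,
            synapse_count_sampler=sd.geometric_synapse_counts(0.5))
        _, _, w = conn.edges()
        assert w.min() >= 1 and w.max() > 1


class TestPlanting:
    def test_single_motif_on_empty_base(self):
        neurons = sd.make_neurons(60, 0, seed=0)
        spec = sd.PlantSpec(dim=2, n_motifs=1, source_pool_size=1,
                            target_pool_size=30)
        conn, log = sd.plant_divergent_simplices(empty_connectome(neurons), spec,
                                                 seed=1)
        assert conn.n_edges == 3 and len(log) == 3

    def test_planting_is_idempotent(self):
        neurons = sd.make_neurons(60, 0, seed=0)
        spec = sd.PlantSpec(dim=3, n_motifs=4, source_pool_size=2,
                            target_pool_size=30)
        once, _ = sd.plant_divergent_simplices(empty_connectome(neurons), spec,
                                               seed=9)
        twice, _ = sd.plant_divergent_simplices(once, spec, seed=9)
        assert (once.adjacency != twice.adjacency).nnz == 0

    def test_pool_exhaustion_raises(self):
        neurons = sd.make_neurons(10, 0, seed=0)
        spec = sd.PlantSpec(dim=4, n_motifs=30, source_pool_size=3,
                            target_pool_size=5)
        with pytest.raises(ValueError, match="pool exhaustion"):
            sd.plant_divergent_simplices(empty_connectome(neurons), spec, seed=0)

    def test_unique_fraction_rises_downstream(self):
        from simplicia.simplices import unique_fraction_by_position

        neurons = sd.make_neurons(100, 0, seed=3)
        spec = sd.PlantSpec(dim=4, n_motifs=10, source_pool_size=3,
                            target_pool_size=50)
        conn, _ = sd.plant_divergent_simplices(empty_connectome(neurons), spec,
                                               seed=4)
        table = enumerate_simplices(conn, max_dim=4)
        _, norm = unique_fraction_by_position(table, 4)
        assert np.all(np.diff(norm) > 0)


class TestBiasedInhibition:
    def test_empty_simplex_table_rejected(self, planted_connectome):
        from simplicia.simplices import SimplexTable

        spec = planted_connectome["spec"]
        with pytest.raises(ValueError, match="empty simplex table"):
            sd.wire_biased_inhibition(
                planted_connectome["conn"], SimplexTable(by_dim={}), spec, seed=0)

    def test_zero_bias_profile_flat(self):
        from simplicia.inhibition_topology import inhibitory_degree_by_position

        neurons = sd.make_neurons(150, 60, seed=10)
        spec = sd.PlantSpec(dim=4, n_motifs=12, source_pool_size=4,
                            target_pool_size=60, in_bias=0.0, out_bias=0.0,
                            loop_back_p=0.0, ei_base_p=0.3, ie_base_p=0.3)
        n = len(neurons)
        base = Connectome(neurons, sp.csr_matrix((n, n), dtype=np.int64))
        planted, _ = sd.plant_divergent_simplices(base, spec, seed=11)
        table = enumerate_simplices(planted.excitatory_subgraph(), max_dim=4)
        conn, _ = sd.wire_biased_inhibition(planted, table, spec, seed=12)
        prof = inhibitory_degree_by_position(conn, table, 4)
        expect = 0.3 * 60
        assert np.abs(prof["in"] - expect).max() < 4 * np.sqrt(expect * 0.7)
        assert np.abs(prof["out"] - expect).max() < 4 * np.sqrt(expect * 0.7)

    def test_strong_bias_recovered_in_profile(self, planted_connectome):
        from simplicia.inhibition_topology import inhibitory_degree_by_position

        conn = planted_connectome["conn"]
        table = planted_connectome["table"]
        dim = planted_connectome["spec"].dim
        prof = inhibitory_degree_by_position(conn, table, dim)
        assert prof["out"].iloc[0] > prof["out"].iloc[dim]   # sources excite I
        assert prof["in"].iloc[dim] > prof["in"].iloc[0]     # targets inhibited

    def test_disinhibitory_fraction_flagged(self, planted_connectome):
        from simplicia.inhibition_topology import inhibitory_targeting_test

        res = inhibitory_targeting_test(planted_connectome["conn"], threshold=1e-6)
        planted = set(planted_connectome["dis_ids"].tolist())
        flagged = set(res.flagged_ids.tolist())
        assert planted <= flagged
        n_i = planted_connectome["conn"].class_mask("I").sum()
        assert res.flagged_fraction == pytest.approx(len(planted) / n_i, abs=0.05)


class TestActivity:
    def test_zero_profile_gives_near_zero_correlation(self):
        nodes = np.arange(40)
        edges = {(i, i + 1): 1 for i in range(0, 38, 2)}
        tr = sd.synth_activity(nodes, edges, {1: 0.0}, T=4000, seed=0)
        C = tr.corr().to_numpy()
        off = ~np.eye(40, dtype=bool)
        assert abs(C[off].mean()) < 0.01

    def test_profile_recovered_within_tolerance(self):
        rng = np.random.default_rng(1)
        nodes = np.arange(200)
        edges = {}
        for i in range(0, 100, 2):
            edges[(i, i + 1)] = 1
        for i in range(100, 200, 2):
            edges[(i, i + 1)] = 5
        profile = {1: 0.05, 5: 0.3}
        tr = sd.synth_activity(nodes, edges, profile, T=10_000, seed=2)
        C = tr.corr()
        got = {d: np.mean([C.loc[u, v] for (u, v), dd in edges.items() if dd == d])
               for d in (1, 5)}
        assert got[1] == pytest.approx(0.05, abs=0.02)
        assert got[5] == pytest.approx(0.3, abs=0.02)

    def test_traces_nonnegative_and_reproducible(self):
        nodes = np.arange(10)
        tr1 = sd.synth_activity(nodes, {(0, 1): 2}, {2: 0.2}, T=500, seed=3)
        tr2 = sd.synth_activity(nodes, {(0, 1): 2}, {2: 0.2}, T=500, seed=3)
        pd.testing.assert_frame_equal(tr1, tr2)
        assert (tr1.to_numpy() >= 0).all()

    def test_invalid_correlation_rejected(self):
        with pytest.raises(ValueError):
            sd.synth_activity(np.arange(4), {(0, 1): 1}, {1: 1.0}, T=100, seed=0)
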