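"""Inhibition tensors, disynaptic matrix, symmetry, overlap, targeting tests."""

import math

import numpy as np
import pandas as pd
import pytest

from simplicia import inhibition_topology as it
from simplicia import null_models as nm
from simplicia.simplices import SimplexTable, enumerate_simplices

from conftest import make_connectome


def simple_fixture():
    """One 2-simplex (0,1,2) plus interneuron 3: 3 synapses 0->3, 2 synapses 3->2."""
    conn = make_connectome(
        4, [(0, 1), (0, 2), (1, 2), (0, 3), (3, 2)],
        classes=["E", "E", "E", "I"], weights=[1, 1, 1, 3, 2])
    table = enumerate_simplices(conn.excitatory_subgraph())
    return conn, table


class TestTensors:
    def test_counts_match_hand_example(self):
        conn, table = simple_fixture()
        t = it.inhibition_tensors(table, 2, conn)
        assert t.m_ei_reduced.toarray().tolist() == [[3]]
        assert t.m_ie_reduced.toarray().tolist() == [[2]]

    def test_uncontacted_interneuron_gives_zero_column(self):
        conn = make_connectome(
            5, [(0, 1), (0, 2), (1, 2), (0, 3), (3, 2)],
            classes=["E", "E", "E", "I", "I"], weights=[1, 1, 1, 3, 2])
        table = enumerate_simplices(conn.excitatory_subgraph())
        t = it.inhibition_tensors(table, 2, conn)
        assert t.m_ei_reduced.toarray()[0, 1] == 0
        assert t.m_ie_reduced.toarray()[0, 1] == 0

    def test_tensor_equals_triple_loop_oracle(self, planted_connectome):
        conn = planted_connectome["conn"]
        table = planted_connectome["table"]
        dim = planted_connectome["spec"].dim
        t = it.inhibition_tensors(table, dim, conn)
        simp = table.simplices(dim)[:15]
        adj = conn.adjacency.toarray()
        idx = {int(v): k for k, v in enumerate(conn.node_ids)}
        for i, row in enumerate(simp):
            slab_ei = t.slab("ei", i)
            slab_ie = t.slab("ie", i)
            for j in range(dim + 1):
                for k, inh in enumerate(t.inh_ids):
                    assert slab_ei[j, k] == adj[idx[int(row[j])], idx[int(inh)]]
                    assert slab_ie[j, k] == adj[idx[int(inh)], idx[int(row[j])]]

    def test_no_simplices_raises(self):
        conn, table = simple_fixture()
        with pytest.raises(ValueError):
            it.inhibition_tensors(table, 5, conn)


class TestDegreeProfile:
    def test_target_only_innervation(self):
        conn, table = simple_fixture()
        prof = it.inhibitory_degree_by_position(conn, table, 2)
        assert prof["in"].tolist() == [0, 0, 1]   # only node 2 receives from I
        assert prof["out"].tolist() == [1, 0, 0]  # only node 0 projects to I

    def test_edge_profile_is_two_point(self):
        conn, table = simple_fixture()
        prof = it.inhibitory_degree_by_position(conn, table, 1)
        assert len(prof) == 2


class TestDisynaptic:
    def test_product_of_hand_example(self):
        conn, table = simple_fixture()
        t = it.inhibition_tensors(table, 2, conn)
        assert it.disynaptic_inhibition(t).tolist() == [[6]]

    def test_matches_explicit_path_sum(self, planted_connectome):
        conn = planted_connectome["conn"]
        table = planted_connectome["table"]
        dim = planted_connectome["spec"].dim
        t = it.inhibition_tensors(table, dim, conn)
        I = it.disynaptic_inhibition(t)
        ei = t.m_ei_reduced.toarray()
        ie = t.m_ie_reduced.toarray()
        S = t.n_simplices
        oracle = np.zeros((S, S), dtype=np.int64)
        for i in range(S):
            for j in range(S):
                oracle[i, j] = sum(int(ei[i, k]) * int(ie[j, k])
                                   for k in range(ei.shape[1]))
        assert np.array_equal(I, oracle)
        # total path count identity, also invariant structure used by shuffles
        assert I.sum() == (ei.sum(0) * ie.sum(0)).sum()

    def test_binarized_variant(self):
        conn, table = simple_fixture()
        t = it.inhibition_tensors(table, 2, conn)
        assert it.disynaptic_inhibition(t, binarize=True).tolist() == [[1]]


class TestSymmetry:
    def test_symmetric_matrix_scores_zero(self):
        rng = np.random.default_rng(0)
        A = rng.random((50, 50))
        assert it.symmetry_score(A + A.T) == pytest.approx(0.0, abs=1e-12)

    def test_hand_computed_two_by_two(self):
        assert it.symmetry_score(np.array([[0.0, 1.0], [3.0, 0.0]])) == 4.0

    def test_iid_entries_score_two(self):
        rng = np.random.default_rng(1)
        scores = [it.symmetry_score(rng.random((200, 200))) for _ in range(100)]
        assert np.mean(scores) == pytest.approx(2.0, rel=0.02)

    def test_constant_matrix_missing_value(self):
        with pytest.warns(UserWarning):
            assert np.isnan(it.symmetry_score(np.ones((3, 3))))

    def test_shuffled_tensors_score_near_two(self):
        # homogeneous random tensors: entries of I at (i,j) and (j,i) are
        # independent, so the shuffle-control symmetry concentrates near 2
        rng = np.random.default_rng(2)
        ei = rng.integers(0, 3, (200, 40))
        ie = rng.integers(0, 3, (200, 40))
        scores = []
        for s in range(20):
            s_ei, s_ie = nm.shuffle_inhibition_columns(ei, ie, seed=s)
            scores.append(it.symmetry_score(s_ei @ s_ie.T))
        assert np.mean(scores) == pytest.approx(2.0, rel=0.10)


class TestOverlap:
    def test_identical_and_disjoint(self):
        table = SimplexTable(by_dim={2: np.array([[0, 1, 2], [0, 1, 2],
                                                  [3, 4, 5]])})
        O = it.overlap_matrix(table, 2, 0, 2)
        assert O[0, 1] == 3 and O[0, 2] == 0
        assert np.array_equal(np.diag(O), [3, 3, 3])

    def test_matches_set_intersection_oracle(self, planted_connectome):
        table = planted_connectome["table"]
        dim = planted_connectome["spec"].dim
        O = it.overlap_matrix(table, dim, 0, 2)
        simp = table.simplices(dim)
        for s in range(min(12, len(simp))):
            for t in range(min(12, len(simp))):
                expect = len(set(simp[s, :3]) & set(simp[t, :3]))
                assert O[s, t] == expect

    def test_range_validation(self):
        table = SimplexTable(by_dim={2: np.array([[0, 1, 2]])})
        with pytest.raises(ValueError):
            it.overlap_matrix(table, 2, 2, 1)


class TestOverlapCorrelation:
    def test_proportional_matrices_correlate_fully(self):
        rng = np.random.default_rng(3)
        O = rng.integers(0, 4, (20, 20))
        O = O + O.T
        corr = it.overlap_inhibition_correlation(O, rng.integers(0, 4, (20, 20)),
                                                 3.0 * O)
        assert corr["source_inhibition"] == pytest.approx(1.0)

    def test_independent_matrices_uncorrelated(self):
        rng = np.random.default_rng(4)
        n = 40
        out = it.overlap_inhibition_correlation(
            rng.random((n, n)), rng.random((n, n)), rng.random((n, n)))
        bound = 3 / math.sqrt(n * (n - 1))
        assert abs(out["source_inhibition"]) < bound
        assert abs(out["target_inhibition"]) < bound

    def test_constant_input_missing(self):
        with pytest.warns(UserWarning):
            out = it.overlap_inhibition_correlation(
                np.ones((5, 5)), np.eye(5), np.eye(5))
        assert np.isnan(out["source_inhibition"])

    def test_source_shared_inhibition_dominates(self):
        """Interneurons excited by shared sources and projecting to the
        simplices' targets make disynaptic inhibition track source overlap
        more strongly than target overlap."""
        from simplicia import synthetic_data as sd
        from simplicia.simplices import enumerate_simplices

        neurons = sd.make_neurons(400, 80, (400.0, 400.0, 400.0), seed=55)
        import scipy.sparse as sp
        from simplicia.core_model import Connectome

        base = Connectome(neurons, sp.csr_matrix((480, 480), dtype=np.int64))
        spec = sd.PlantSpec(dim=5, n_motifs=40, source_pool_size=8,
                            target_pool_size=260, in_bias=4.0, out_bias=0.0,
                            ei_base_p=0.02, ie_base_p=0.005, loop_back_p=0.5)
        planted, _ = sd.plant_divergent_simplices(base, spec, seed=56)
        table = enumerate_simplices(planted.excitatory_subgraph(), max_dim=5)
        conn, _ = sd.wire_biased_inhibition(planted, table, spec, seed=57)
        t = it.inhibition_tensors(table, 5, conn)
        I = it.disynaptic_inhibition(t)
        o_src = it.overlap_matrix(table, 5, 0, 2)
        o_tgt = it.overlap_matrix(table, 5, 3, 5)
        corr = it.overlap_inhibition_correlation(o_src, o_tgt, I)
        assert corr["source_inhibition"] > corr["target_inhibition"]


class TestTargeting:
    def test_zero_inhibitory_outdegree_gives_p_one(self):
        conn = make_connectome(4, [(2, 0), (3, 0), (3, 1)],
                               classes=["E", "E", "I", "I"])
        res = it.inhibitory_targeting_test(conn)
        assert (res.table["p_value"] == 1.0).all()

    def test_p_value_equals_direct_tail_enumeration(self):
        # pool M=10 slots, N=5 inhibitory, neuron draws n=4, observes 4
        p_direct = sum(
            math.comb(5, k) * math.comb(5, 4 - k) / math.comb(10, 4)
            for k in range(4, 5)
        )
        from scipy.stats import hypergeom

        assert hypergeom.sf(3, 10, 5, 4) == pytest.approx(p_direct)
        assert p_direct == pytest.approx(5 / 210)

    def test_flags_planted_disinhibitory_class(self, planted_connectome):
        res = it.inhibitory_targeting_test(planted_connectome["conn"],
                                           threshold=1e-6)
        planted = set(planted_connectome["dis_ids"].tolist())
        assert planted <= set(res.flagged_ids.tolist())
        # false positives bounded: non-planted flagged neurons are rare
        extra = set(res.flagged_ids.tolist()) - planted
        assert len(extra) <= 2

    def test_invariants(self, planted_connectome):
        res = it.inhibitory_targeting_test(planted_connectome["conn"])
        t = res.table
        assert (t["d_inh"] <= t["d_ttl"]).all()
        assert t["p_value"].between(0, 1).all()


class TestSimplexDegrees:
    def test_multiplicity_counted_per_simplex(self):
        # interneuron 4 receives from node 0 which sits at position 0 of BOTH
        # triangles (0,1,2) and (0,1,3)
        conn = make_connectome(
            5, [(0, 1), (0, 2), (1, 2), (0, 3), (1, 3), (0, 4)],
            classes=["E"] * 4 + ["I"])
        table = enumerate_simplices(conn.excitatory_subgraph())
        deg = it.simplex_degrees_of_inhibitory(
            conn, table, 2, source_positions=(0, 1), target_positions=(2,))
        assert deg["simplex_indegree"].iloc[0] == 2

    def test_indegree_from_two_positions_of_one_simplex(self):
        conn = make_connectome(
            4, [(0, 1), (0, 2), (1, 2), (0, 3), (2, 3)],
            classes=["E", "E", "E", "I"])
        table = enumerate_simplices(conn.excitatory_subgraph())
        deg = it.simplex_degrees_of_inhibitory(
            conn, table, 2, source_positions=(0, 1, 2), target_positions=())
        assert deg["simplex_indegree"].iloc[0] == 2

    def test_equals_loop_oracle(self, planted_connectome):
        conn = planted_connectome["conn"]
        table = planted_connectome["table"]
        dim = planted_connectome["spec"].dim
        deg = it.simplex_degrees_of_inhibitory(
            conn, table, dim, source_positions=(0, 1, 2),
            target_positions=(dim - 2, dim - 1, dim))
        simp = table.simplices(dim)
        adj = conn.adjacency.toarray() > 0
        idx = {int(v): k for k, v in enumerate(conn.node_ids)}
        inh = deg["neuron_id"].to_numpy()
        for k in np.random.default_rng(0).choice(len(inh), 10, replace=False):
            ki = idx[int(inh[k])]
            expect_in = sum(
                adj[idx[int(simp[i, p])], ki]
                for i in range(len(simp)) for p in (0, 1, 2))
            expect_out = sum(
                adj[ki, idx[int(simp[i, p])]]
                for i in range(len(simp)) for p in (dim - 2, dim - 1, dim))
            assert deg["simplex_indegree"].iloc[k] == expect_in
            assert deg["simplex_outdegree"].iloc[k] == expect_out


class TestDisinhibitionProfile:
    def test_no_flagged_neurons_share_zero(self):
        conn = make_connectome(
            6, [(0, 1), (0, 2), (1, 2), (3, 4), (4, 5)],
            classes=["E", "E", "E", "I", "I", "I"])
        table = enumerate_simplices(conn.excitatory_subgraph())
        res = it.inhibitory_targeting_test(conn, threshold=1e-30)
        deg = it.simplex_degrees_of_inhibitory(conn, table, 2,
                                               source_positions=(0, 1, 2),
                                               target_positions=(2,))
        prof = it.disinhibition_profile(conn, res, deg, bins=2)
        share = prof["targeting_share"].dropna()
        assert (share == 0).all() or len(share) == 0

    def test_share_rises_with_simplex_degree(self, planted_connectome):
        conn = planted_connectome["conn"]
        table = planted_connectome["table"]
        dim = planted_connectome["spec"].dim
        res = it.inhibitory_targeting_test(conn, threshold=1e-6)
        deg = it.simplex_degrees_of_inhibitory(conn, table, dim)
        prof = it.disinhibition_profile(conn, res, deg, bins=3)
        share = prof["targeting_share"].dropna().to_numpy()
        assert len(share) >= 2 and share[-1] >= share[0] - 0.05


class TestStratifiedProfiles:
    def test_single_class_equals_degree_over_size(self, planted_connectome):
        conn = planted_connectome["conn"]
        table = planted_connectome["table"]
        dim = planted_connectome["spec"].dim
        i_ids = conn.node_ids[conn.class_mask("I")]
        labels = pd.Series("inh", index=i_ids)
        prof = it.position_profile_stratified(conn, table, dim, labels,
                                              direction="onto_simplex")
        ref = it.inhibitory_degree_by_position(conn, table, dim)
        assert np.allclose(prof["inh"], ref["in"] / len(i_ids))

    def test_empty_class_warns(self, planted_connectome):
        conn = planted_connectome["conn"]
        table = planted_connectome["table"]
        dim = planted_connectome["spec"].dim
        labels = pd.Series(["a"] * 3 + ["ghost"] * 0,
                           index=conn.node_ids[conn.class_mask("I")][:3])
        labels = pd.concat([labels, pd.Series(["ghost"], index=[10**9])])
        with pytest.warns(UserWarning, match="empty class"):
            prof = it.position_profile_stratified(conn, table, dim, labels)
        assert prof["ghost"].isna().all()


class TestSynapsesPerConnection:
    def test_unit_weights_give_constant_one(self):
        conn, table = simple_fixture()
        conn2 = make_connectome(
            4, [(0, 1), (0, 2), (1, 2), (0, 3), (3, 2)],
            classes=["E", "E", "E", "I"])
        table2 = enumerate_simplices(conn2.excitatory_subgraph())
        prof = it.synapses_per_connection_by_position(conn2, table2, 2)
        assert prof["ei"].dropna().eq(1.0).all()
        assert prof["ie"].dropna().eq(1.0).all()

    def test_single_heavy_connection_at_target(self):
        conn = make_connectome(
            4, [(0, 1), (0, 2), (1, 2), (3, 2)],
            classes=["E", "E", "E", "I"], weights=[1, 1, 1, 5])
        table = enumerate_simplices(conn.excitatory_subgraph())
        prof = it.synapses_per_connection_by_position(conn, table, 2)
        assert prof["ie"].iloc[2] == 5.0

    def test_equals_direct_aggregation(self, planted_connectome):
        conn = planted_connectome["conn"]
        table = planted_connectome["table"]
        dim = planted_connectome["spec"].dim
        prof = it.synapses_per_connection_by_position(conn, table, dim)
        simp = table.simplices(dim)
        adj = conn.adjacency.toarray()
        idx = {int(v): k for k, v in enumerate(conn.node_ids)}
        i_pos = np.flatnonzero(conn.class_mask("I"))
        for p in (0, dim):
            weights = []
            for row in simp:
                node = idx[int(row[p])]
                weights.extend(adj[node, i_pos][adj[node, i_pos] > 0])
            assert prof["ei"].iloc[p] == pytest.approx(np.mean(weights))
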