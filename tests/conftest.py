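"""Shared fixtures: tiny deterministic graphs and synthetic connectome builders."""

from __future__ import annotations

import itertools

import numpy as np
import pandas as pd
import pytest
import scipy.sparse as sp

from simplicia.core_model import Connectome


def make_connectome(n, edges, classes=None, positions=None, weights=None):
    """Build a small Connectome from an explicit edge list (by node index)."""
    classes = classes or ["E"] * n
    if positions is None:
        rng = np.random.default_rng(12345)
        positions = rng.uniform(0, 100, size=(n, 3))
    nodes = pd.DataFrame({
        "neuron_id": np.arange(n, dtype=np.int64),
        "x": np.asarray(positions)[:, 0],
        "y": np.asarray(positions)[:, 1],
        "z": np.asarray(positions)[:, 2],
        "synapse_class": np.asarray(classes, dtype=object),
    })
    if edges:
        pre, post = map(np.asarray, zip(*edges))
        w = np.asarray(weights) if weights is not None else np.ones(len(pre), dtype=np.int64)
    else:
        pre = post = np.array([], dtype=np.int64)
        w = np.array([], dtype=np.int64)
    adj = sp.coo_matrix((w, (pre, post)), shape=(n, n)).tocsr()
    return Connectome(nodes, adj)


def transitive_tournament(k):
    """Complete DAG on k nodes: edge i -> j iff i < j."""
    return make_connectome(k, [(i, j) for i in range(k) for j in range(i + 1, k)])


def brute_force_simplices(conn, max_dim):
    """Independent oracle: check every ordered node subset against the
    all-pairs edge requirement."""
    adj = conn.adjacency.toarray() > 0
    ids = conn.node_ids
    n = conn.n_nodes
    out = {0: [(int(i),) for i in ids]}
    for dim in range(1, max_dim + 1):
        found = []
        for combo in itertools.permutations(range(n), dim + 1):
            if all(adj[combo[i], combo[j]]
                   for i in range(dim + 1) for j in range(i + 1, dim + 1)):
                found.append(tuple(int(ids[c]) for c in combo))
        out[dim] = found
    return out


@pytest.fixture(scope="session")
def random_graph_30():
    """Directed ER graph, n=30, p≈0.3, fixed seed."""
    rng = np.random.default_rng(77)
    n = 30
    mask = rng.random((n, n)) < 0.3
    np.fill_diagonal(mask, False)
    edges = list(zip(*np.nonzero(mask)))
    return make_connectome(n, [(int(u), int(v)) for u, v in edges])


@pytest.fixture(scope="session")
def planted_connectome():
    """Synthetic connectome with planted divergent simplices, biased inhibition
    and a disinhibitory class; shared across recovery tests."""
    from simplicia import synthetic_data as sd
    from simplicia.simplices import enumerate_simplices

    neurons = sd.make_neurons(400, 80, (400.0, 400.0, 400.0), seed=101)
    base = sd.sample_distance_connectome(
        neurons, sd.DistanceModelParams.uniform(0.03, 150.0), seed=102)
    spec = sd.PlantSpec(disinhibitory_fraction=0.15)
    planted, _ = sd.plant_divergent_simplices(base, spec, seed=103)
    table = enumerate_simplices(planted.excitatory_subgraph(), max_dim=spec.dim)
    conn, dis_ids = sd.wire_biased_inhibition(planted, table, spec, seed=104)
    return {"conn": conn, "table": table, "spec": spec, "dis_ids": dis_ids}
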