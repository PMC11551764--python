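"""Control connectomes and shuffles.

Four nulls back the analyses: (i) per-pathway exponential distance-dependent
models fit to an observed connectome and re-instantiated stochastically;
(ii) the directed configuration model (in/out-degree preserving double-edge
swaps); (iii) directed Erdos-Renyi graphs with an exact edge count; and
(iv) the column-shuffle control for the simplex-by-interneuron matrices, which
preserves every simplex's inhibitory in- and out-degree totals while
destroying interneuron identity.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.sparse as sp
from scipy.optimize import curve_fit

from .core_model import Connectome, validate_neuron_table
from .synthetic_data import DistanceModelParams, sample_distance_connectome

__all__ = [
    "FittedDistanceModel",
    "fit_distance_model",
    "instantiate_distance_model",
    "configuration_model",
    "erdos_renyi_directed",
    "shuffle_inhibition_columns",
]


@dataclass
class FittedDistanceModel:
    """Fitted exponential decay P(d) = a exp(-d/b) for one pathway, with the
    binned empirical probabilities it was fit to."""

    pathway: str
    a: float
    b: float
    bin_edges: np.ndarray
    bin_probability: np.ndarray
    bin_n_pairs: np.ndarray
    residuals: np.ndarray

    def probability(self, d: np.ndarray) -> np.ndarray:
        return self.a * np.exp(-np.asarray(d, dtype=float) / self.b)


def _pathway_masks(neurons: pd.DataFrame, pathway: str) -> tuple[np.ndarray, np.ndarray]:
    is_i = (neurons["synapse_class"] == "I").to_numpy()
    pre = is_i if pathway[0] == "I" else ~is_i
    post = is_i if pathway[1] == "I" else ~is_i
    return pre, post


def fit_distance_model(
    conn: Connectome,
    pathway: str = "EE",
    bin_width: float = 20.0,
    max_distance: float | None = None,
) -> FittedDistanceModel:
    """Fit (a, b) to the observed distance-dependent connection probability of
    one pathway by nonlinear least squares on binned probabilities.

    Distances are binned in ``bin_width``-um bins up to ``max_distance``
    (default: the 99th percentile of pairwise distances in the pathway); both
    parameters are constrained positive. An all-zero pathway returns a = 0 with
    a warning.
    """
    neurons = conn.nodes
    pre_mask, post_mask = _pathway_masks(neurons, pathway)
    pre_idx = np.flatnonzero(pre_mask)
    post_idx = np.flatnonzero(post_mask)
    if len(pre_idx) == 0 or len(post_idx) == 0:
        raise ValueError(f"no neurons for pathway {pathway}")
    xyz = conn.positions
    d = np.sqrt(
        ((xyz[pre_idx][:, None, :] - xyz[post_idx][None, :, :]) ** 2).sum(axis=-1)
    )
    connected = (conn.adjacency[pre_idx][:, post_idx] > 0).toarray()
    valid = pre_idx[:, None] != post_idx[None, :]
    d_flat = d[valid]
    c_flat = connected[valid]
    if max_distance is None:
        max_distance = float(np.percentile(d_flat, 99.0))
    edges = np.arange(0.0, max_distance + bin_width, bin_width)
    which = np.digitize(d_flat, edges) - 1
    nbins = len(edges) - 1
    n_pairs = np.zeros(nbins)
    n_conn = np.zeros(nbins)
    ok = (which >= 0) & (which < nbins)
    np.add.at(n_pairs, which[ok], 1)
    np.add.at(n_conn, which[ok], c_flat[ok])
    with np.errstate(invalid="ignore", divide="ignore"):
        p_emp = np.where(n_pairs > 0, n_conn / np.maximum(n_pairs, 1), np.nan)
    centers = 0.5 * (edges[:-1] + edges[1:])
    use = n_pairs > 0

    if n_conn.sum() == 0:
        warnings.warn(f"pathway {pathway}: no connections; returning a=0", stacklevel=2)
        return FittedDistanceModel(pathway, 0.0, 1.0, edges, p_emp, n_pairs,
                                   np.zeros(nbins))

    def model(d_, a, b):
        return a * np.exp(-d_ / b)

    p0 = (max(float(np.nanmax(p_emp[use])), 1e-3), max(max_distance / 3.0, 1.0))
    # weight bins by their pair counts: sparse near-distance bins carry large
    # binomial noise and would otherwise destabilize the amplitude
    sigma = 1.0 / np.sqrt(n_pairs[use])
    popt, _ = curve_fit(
        model, centers[use], p_emp[use], p0=p0, sigma=sigma,
        bounds=([1e-12, 1e-6], [1.0, np.inf]), maxfev=20000,
    )
    a, b = float(popt[0]), float(popt[1])
    resid = np.full(nbins, np.nan)
    resid[use] = p_emp[use] - model(centers[use], a, b)
    return FittedDistanceModel(pathway, a, b, edges, p_emp, n_pairs, resid)


def fit_all_pathways(conn: Connectome, bin_width: float = 20.0
                     ) -> DistanceModelParams:
    """Fit the four E/I pathway models and bundle them as generator params."""
    fitted = {}
    for pw in ("EE", "EI", "IE", "II"):
        try:
            m = fit_distance_model(conn, pw, bin_width=bin_width)
            fitted[pw] = (max(m.a, 1e-12), m.b)
        except ValueError:
            fitted[pw] = (1e-12, 1.0)
    return DistanceModelParams(params=fitted)


def instantiate_distance_model(
    neurons: pd.DataFrame,
    params: DistanceModelParams,
    seed: int | np.random.Generator = 0,
) -> Connectome:
    """Stochastic instance of a fitted distance model; identical contract to
    :func:`simplicia.synthetic_data.sample_distance_connectome` (shared
    implementation)."""
    return sample_distance_connectome(neurons, params, seed=seed)


def configuration_model(
    graph: Connectome,
    seed: int | np.random.Generator = 0,
    n_swaps_per_edge: int = 10,
) -> Connectome:
    """Degree-preserving randomization by directed double-edge swaps.

    Repeatedly picks two edges (u, v), (x, y) and rewires to (u, y), (x, v),
    rejecting swaps that would create self-loops or multi-edges, until
    ``n_swaps_per_edge * |E|`` swaps are accepted. In- and out-degree sequences
    are exactly preserved; weights travel with the source endpoint's edge slot.
    """
    m = graph.n_edges
    if m < 2:
        warnings.warn("graph has < 2 edges; returning unchanged", stacklevel=2)
        return graph.with_adjacency(graph.adjacency.copy())
    rng = np.random.default_rng(seed)
    coo = graph.adjacency.tocoo()
    pre = coo.row.copy()
    post = coo.col.copy()
    w = coo.data.copy()
    present = set(zip(pre.tolist(), post.tolist()))
    target = n_swaps_per_edge * m
    accepted = 0
    max_tries = 200 * target
    tries = 0
    while accepted < target and tries < max_tries:
        tries += 1
        e1, e2 = rng.integers(0, m, size=2)
        if e1 == e2:
            continue
        u, v = int(pre[e1]), int(post[e1])
        x, y = int(pre[e2]), int(post[e2])
        if u == y or x == v:
            continue
        if (u, y) in present or (x, v) in present:
            continue
        present.discard((u, v))
        present.discard((x, y))
        present.add((u, y))
        present.add((x, v))
        post[e1], post[e2] = y, v
        accepted += 1
    if accepted < target:
        warnings.warn(
            f"configuration model accepted only {accepted}/{target} swaps "
            "(graph too constrained)", stacklevel=2,
        )
    adj = sp.coo_matrix((w, (pre, post)), shape=graph.adjacency.shape).tocsr()
    return graph.with_adjacency(adj)


def erdos_renyi_directed(
    n: int, m_edges: int, seed: int | np.random.Generator = 0,
    neurons: pd.DataFrame | None = None,
) -> Connectome:
    """Directed ER graph: exactly ``m_edges`` distinct ordered pairs without
    self-loops, uniform without replacement. Node table defaults to E neurons
    at the origin (positions are irrelevant for this null)."""
    max_m = n * (n - 1)
    if not (0 <= m_edges <= max_m):
        raise ValueError(f"m_edges must be in [0, {max_m}]")
    rng = np.random.default_rng(seed)
    # sample ordered pairs by index into the n*(n-1) off-diagonal slots
    slots = rng.choice(max_m, size=m_edges, replace=False) if m_edges else np.array([], dtype=np.int64)
    pre = slots // (n - 1)
    rem = slots % (n - 1)
    post = rem + (rem >= pre)  # skip the diagonal
    if neurons is None:
        neurons = pd.DataFrame(
            {
                "neuron_id": np.arange(n, dtype=np.int64),
                "x": 0.0, "y": 0.0, "z": 0.0,
                "synapse_class": "E",
            }
        )
    adj = sp.coo_matrix(
        (np.ones(m_edges, dtype=np.int64), (pre, post)), shape=(n, n)
    ).tocsr()
    return Connectome(neurons, adj, meta={"generator": "erdos_renyi"})


def shuffle_inhibition_columns(
    m_ei_reduced: np.ndarray | sp.spmatrix,
    m_ie_reduced: np.ndarray | sp.spmatrix,
    seed: int | np.random.Generator = 0,
) -> tuple[np.ndarray | sp.spmatrix, np.ndarray | sp.spmatrix]:
    """Independently permute the interneuron columns of the simplex-by-
    interneuron matrices M'_ei and M'_ie.

    Row sums — each simplex's total inhibitory in/out synapse counts — are
    untouched, so the resulting disynaptic-inhibition null preserves per-simplex
    inhibitory degrees while scrambling which interneurons mediate them.
    """
    if m_ei_reduced.shape[1] != m_ie_reduced.shape[1]:
        raise ValueError("matrices must share the interneuron column count")
    rng = np.random.default_rng(seed)
    perm_ei = rng.permutation(m_ei_reduced.shape[1])
    perm_ie = rng.permutation(m_ie_reduced.shape[1])
    if sp.issparse(m_ei_reduced):
        return m_ei_reduced.tocsc()[:, perm_ei].tocsr(), \
            m_ie_reduced.tocsc()[:, perm_ie].tocsr()
    return np.asarray(m_ei_reduced)[:, perm_ei], np.asarray(m_ie_reduced)[:, perm_ie]
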