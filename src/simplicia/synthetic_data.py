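"""Synthetic connectomes and activity traces with the statistical structure the
downstream analyses assume.

The generator emulates, in order of assembly: a uniform soma point cloud in a
cortical slab; independent distance-dependent connectivity per E/I pathway with
decaying-exponential probability P(d) = a exp(-d/b); planted divergent
feed-forward simplicial motifs (few reused sources, many unique targets);
inhibitory connectivity biased by simplex position (interneurons excited from
source positions, innervating target positions) including a disinhibitory
subpopulation wired preferentially onto other interneurons; and nonnegative
activity traces whose pairwise correlation rises with the maximal simplex
dimension of the connecting edge.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.sparse as sp

from .core_model import Connectome, validate_neuron_table
from .simplices import SimplexTable

__all__ = [
    "DistanceModelParams",
    "PlantSpec",
    "make_neurons",
    "sample_distance_connectome",
    "plant_divergent_simplices",
    "wire_biased_inhibition",
    "synth_activity",
]

PATHWAYS = ("EE", "EI", "IE", "II")


@dataclass
class DistanceModelParams:
    """Per-pathway exponential distance-decay parameters.

    Each pathway (E->E, E->I, I->E, I->I) carries an amplitude ``a`` in (0, 1]
    and a length constant ``b`` > 0 (um), with connection probability
    ``P(d) = a * exp(-d / b)`` at soma distance ``d``.
    """

    params: dict[str, tuple[float, float]] = field(
        default_factory=lambda: {p: (0.1, 100.0) for p in PATHWAYS}
    )

    def __post_init__(self):
        for pw, (a, b) in self.params.items():
            if pw not in PATHWAYS:
                raise ValueError(f"unknown pathway {pw!r}")
            if not (0.0 <= a <= 1.0):
                raise ValueError(f"{pw}: amplitude a={a} outside [0, 1]")
            if b <= 0:
                raise ValueError(f"{pw}: length constant b={b} must be > 0")

    def probability(self, pathway: str, d: np.ndarray) -> np.ndarray:
        a, b = self.params[pathway]
        return a * np.exp(-np.asarray(d, dtype=float) / b)

    @classmethod
    def uniform(cls, a: float, b: float) -> "DistanceModelParams":
        return cls(params={p: (a, b) for p in PATHWAYS})


@dataclass
class PlantSpec:
    """Specification of planted motifs and position-biased inhibition.

    ``dim`` and ``n_motifs`` define the divergent feed-forward simplices;
    sources are drawn (with reuse) from a pool of ``source_pool_size``
    excitatory nodes, targets mostly without reuse from ``target_pool_size``
    nodes. ``in_bias`` scales how strongly E->I sampling favors source
    positions and ``out_bias`` how strongly I->E sampling favors target
    positions (0 = flat). ``disinhibitory_fraction`` of interneurons is wired
    preferentially onto other interneurons. ``synapse_boost`` multiplies the
    synapse count of position-favored inhibitory connections.
    """

    dim: int = 5
    n_motifs: int = 25
    source_pool_size: int = 10
    target_pool_size: int = 200
    in_bias: float = 3.0
    out_bias: float = 3.0
    disinhibitory_fraction: float = 0.0
    ei_base_p: float = 0.05
    ie_base_p: float = 0.05
    disinh_ii_p: float = 0.5
    disinh_ie_p: float = 0.02
    disinh_engagement_bias: float = 0.6
    ii_base_p: float = 0.03
    loop_back_p: float = 0.25
    synapse_boost: int = 1

    def __post_init__(self):
        if self.dim < 2:
            raise ValueError("planted motif dimension must be >= 2")
        if not (0.0 <= self.disinhibitory_fraction <= 1.0):
            raise ValueError("disinhibitory_fraction must be in [0, 1]")


def make_neurons(
    n_e: int,
    n_i: int,
    volume: tuple[float, float, float] = (600.0, 600.0, 600.0),
    seed: int | np.random.Generator = 0,
) -> pd.DataFrame:
    """Uniform random soma positions in a rectangular slab (um), with E then I
    class labels; reproducible under ``seed``."""
    if n_e < 0 or n_i < 0:
        raise ValueError("counts must be >= 0")
    if n_e + n_i == 0:
        raise ValueError("need at least one neuron")
    vol = np.asarray(volume, dtype=float)
    if (vol <= 0).any():
        raise ValueError("volume extents must be positive")
    rng = np.random.default_rng(seed)
    n = n_e + n_i
    xyz = rng.uniform(0.0, vol, size=(n, 3))
    table = pd.DataFrame(
        {
            "neuron_id": np.arange(n, dtype=np.int64),
            "x": xyz[:, 0],
            "y": xyz[:, 1],
            "z": xyz[:, 2],
            "synapse_class": np.array(["E"] * n_e + ["I"] * n_i, dtype=object),
        }
    )
    return validate_neuron_table(table).reset_index(drop=True)


def _pathway_labels(neurons: pd.DataFrame) -> np.ndarray:
    return (neurons["synapse_class"] == "I").to_numpy().astype(np.int8)


def sample_distance_connectome(
    neurons: pd.DataFrame,
    params: DistanceModelParams,
    seed: int | np.random.Generator = 0,
    synapse_count_sampler=None,
) -> Connectome:
    """Independent Bernoulli connectivity per ordered pair with pathway-specific
    P(d) = a exp(-d/b); no self-loops.

    ``synapse_count_sampler(rng, n)`` may supply positive integer synapse
    counts per accepted connection (default: constant 1).
    """
    neurons = validate_neuron_table(neurons).reset_index(drop=True)
    rng = np.random.default_rng(seed)
    xyz = neurons[["x", "y", "z"]].to_numpy(float)
    is_i = _pathway_labels(neurons)
    n = len(neurons)
    d = np.sqrt(((xyz[:, None, :] - xyz[None, :, :]) ** 2).sum(axis=-1))
    prob = np.empty((n, n), dtype=float)
    for pre_i in (0, 1):
        for post_i in (0, 1):
            pw = ("E", "I")[pre_i] + ("E", "I")[post_i]
            mask = (is_i[:, None] == pre_i) & (is_i[None, :] == post_i)
            prob[mask] = params.probability(pw, d[mask])
    if (prob > 1.0 + 1e-12).any():
        raise ValueError("configured P(d) exceeds 1")
    np.fill_diagonal(prob, 0.0)
    hit = rng.random((n, n)) < prob
    pre, post = np.nonzero(hit)
    if synapse_count_sampler is None:
        weights = np.ones(len(pre), dtype=np.int64)
    else:
        weights = np.asarray(synapse_count_sampler(rng, len(pre)), dtype=np.int64)
        if len(weights) and weights.min() < 1:
            raise ValueError("synapse counts must be positive")
    adj = sp.coo_matrix((weights, (pre, post)), shape=(n, n)).tocsr()
    return Connectome(neurons, adj, meta={"generator": "distance_model"})


def geometric_synapse_counts(p: float = 0.5):
    """Synapse-count sampler with geometric (heavier-tailed) counts >= 1."""

    def sampler(rng: np.random.Generator, n: int) -> np.ndarray:
        return rng.geometric(p, size=n)

    return sampler


def _add_edges(adj: sp.csr_matrix, pairs: list[tuple[int, int]],
               weights: list[int] | None = None) -> sp.csr_matrix:
    """Set weight on currently-absent edges only (planting keeps the graph
    simple and never increments existing weights)."""
    if not pairs:
        return adj
    lil = adj.tolil()
    for k, (u, v) in enumerate(pairs):
        if u != v and lil[u, v] == 0:
            lil[u, v] = weights[k] if weights is not None else 1
    return lil.tocsr()


def plant_divergent_simplices(
    base: Connectome, spec: PlantSpec, seed: int | np.random.Generator = 0
) -> tuple[Connectome, pd.DataFrame]:
    """Add the edges of ``n_motifs`` ordered feed-forward motifs of dimension
    ``dim`` to ``base``.

    Each position p draws from its own pool of exactly m_p distinct excitatory
    nodes, with m_p interpolating linearly from ``source_pool_size`` at the
    source to ``n_motifs`` at the target position; motifs are assigned pool
    members round-robin (in a per-position random order). Pools are disjoint
    across positions, so the number of distinct neurons occupying position p is
    exactly min(m_p, n_motifs): a few heavily reused sources fan out onto fully
    unique targets — the divergent feed-forward structure, with a strictly
    rising unique-neuron fraction whenever n_motifs >= source_pool_size + dim.
    Returns the new connectome and an edge-addition log. Planting is
    idempotent: already-present edges are left untouched.
    """
    rng = np.random.default_rng(seed)
    e_ids = base.node_ids[base.class_mask("E")]
    dim = spec.dim
    s0 = min(spec.source_pool_size, spec.n_motifs)
    sizes = [int(round(s0 + (spec.n_motifs - s0) * p / dim))
             for p in range(dim + 1)]
    budget = spec.source_pool_size + spec.target_pool_size
    if sum(sizes) > budget:
        raise ValueError(
            f"pool exhaustion: graded pools need {sum(sizes)} nodes, "
            f"budget is {budget}"
        )
    if len(e_ids) < sum(sizes):
        raise ValueError(
            f"pool exhaustion: need {sum(sizes)} excitatory nodes, "
            f"have {len(e_ids)}"
        )
    drawn = rng.choice(e_ids, size=sum(sizes), replace=False)
    pools, offset = [], 0
    for m in sizes:
        pools.append(drawn[offset:offset + m])
        offset += m

    motifs = [
        [int(pools[p][i % sizes[p]]) for p in range(dim + 1)]
        for i in range(spec.n_motifs)
    ]

    pos = {int(i): k for k, i in enumerate(base.node_ids)}
    pairs, log = [], []
    for m_idx, verts in enumerate(motifs):
        for i in range(spec.dim + 1):
            for j in range(i + 1, spec.dim + 1):
                u, v = verts[i], verts[j]
                pairs.append((pos[u], pos[v]))
                log.append((m_idx, u, v))
    adj = _add_edges(base.adjacency.copy(), pairs)
    log_df = pd.DataFrame(log, columns=["motif", "pre_id", "post_id"])
    conn = base.with_adjacency(adj)
    conn.meta = dict(base.meta, planted_motifs=spec.n_motifs, planted_dim=spec.dim)
    return conn, log_df


def wire_biased_inhibition(
    base: Connectome,
    simplices: SimplexTable,
    spec: PlantSpec,
    seed: int | np.random.Generator = 0,
) -> tuple[Connectome, np.ndarray]:
    """Wire inhibition relative to planted simplices with position bias.

    Each excitatory neuron appearing in a simplex of the planted dimension gets
    a mean normalized position pbar in [0, 1] over all its (simplex, position)
    occurrences. E->I edges from it are then sampled once per (node,
    interneuron) pair with probability ``ei_base_p * (1 + in_bias *
    (1 - pbar))`` (favoring source-side neurons) and I->E edges onto it with
    ``ie_base_p * (1 + out_bias * pbar)`` (favoring target-side neurons).
    Sampling per pair rather than per simplex occurrence keeps the
    position-degree profile monotone even though source neurons are reused
    across many simplices. A ``disinhibitory_fraction`` of interneurons is
    additionally wired onto other interneurons with probability
    ``disinh_ii_p`` (and only weakly onto E), emulating a disinhibitory class.
    Position-favored edges carry ``synapse_boost`` synapses. Returns the new
    connectome and the ids of the disinhibitory interneurons.
    """
    dim = spec.dim
    simp = simplices.simplices(dim)
    if len(simp) == 0:
        raise ValueError("empty simplex table: nothing to bias against")
    i_ids = base.node_ids[base.class_mask("I")]
    if len(i_ids) == 0:
        raise ValueError("base connectome has no inhibitory nodes")
    rng = np.random.default_rng(seed)
    pos = {int(nid): k for k, nid in enumerate(base.node_ids)}

    n_dis = int(round(spec.disinhibitory_fraction * len(i_ids)))
    dis_ids = rng.choice(i_ids, size=n_dis, replace=False) if n_dis else np.array([], dtype=np.int64)
    dis_set = set(int(x) for x in dis_ids)
    plain_i = np.array([i for i in i_ids if int(i) not in dis_set], dtype=np.int64)

    # mean normalized position of every neuron occurring in a planted simplex
    occ_sum: dict[int, float] = {}
    occ_n: dict[int, int] = {}
    for row in simp:
        for p in range(dim + 1):
            node = int(row[p])
            occ_sum[node] = occ_sum.get(node, 0.0) + p / dim
            occ_n[node] = occ_n.get(node, 0) + 1

    pairs: list[tuple[int, int]] = []
    weights: list[int] = []
    excited_by: dict[int, np.ndarray] = {}
    for node, total in occ_sum.items():
        pbar = total / occ_n[node]
        p_ei = min(1.0, spec.ei_base_p * (1.0 + spec.in_bias * (1.0 - pbar)))
        p_ie = min(1.0, spec.ie_base_p * (1.0 + spec.out_bias * pbar))
        hit_ei = plain_i[rng.random(len(plain_i)) < p_ei]
        hit_ie = plain_i[rng.random(len(plain_i)) < p_ie]
        excited_by[node] = hit_ei
        w_ei = spec.synapse_boost if pbar <= 0.5 else 1
        w_ie = spec.synapse_boost if pbar >= 0.5 else 1
        for k in hit_ei:
            pairs.append((pos[node], pos[int(k)]))
            weights.append(w_ei)
        for k in hit_ie:
            pairs.append((pos[int(k)], pos[node]))
            weights.append(w_ie)

    # loop-back motif: interneurons excited by a simplex's source side innervate
    # that simplex's target side, so disynaptic inhibition between two simplices
    # scales with their source-side overlap
    if spec.loop_back_p > 0:
        src_hi = min(2, dim - 1)
        tgt_lo = max(src_hi + 1, dim - 2)
        for row in simp:
            targets = [int(v) for v in row[tgt_lo:dim + 1]]
            for a in row[:src_hi + 1]:
                for k in excited_by.get(int(a), ()):
                    for t in targets:
                        if rng.random() < spec.loop_back_p:
                            pairs.append((pos[int(k)], pos[t]))
                            weights.append(1)

    # per-interneuron simplex engagement (planted E<->I partners); the
    # disinhibitory class preferentially inhibits the engaged interneurons
    engagement = {int(k): 0 for k in i_ids}
    for (u, v) in pairs:
        u_id, v_id = int(base.node_ids[u]), int(base.node_ids[v])
        if u_id in engagement:
            engagement[u_id] += 1
        if v_id in engagement:
            engagement[v_id] += 1
    max_eng = max(max(engagement.values()), 1)

    e_ids = base.node_ids[base.class_mask("E")]
    beta = spec.disinh_engagement_bias
    for d in dis_ids:
        others = i_ids[i_ids != d]
        rel = np.array([engagement[int(k)] / max_eng for k in others])
        p_ii = spec.disinh_ii_p * ((1.0 - beta) + beta * rel)
        hit_ii = others[rng.random(len(others)) < p_ii]
        hit_ie = e_ids[rng.random(len(e_ids)) < spec.disinh_ie_p]
        for k in hit_ii:
            pairs.append((pos[int(d)], pos[int(k)]))
            weights.append(1)
        for k in hit_ie:
            pairs.append((pos[int(d)], pos[int(k)]))
            weights.append(1)

    # flat low-rate I->I baseline from the non-disinhibitory population
    for i in plain_i:
        others = i_ids[i_ids != i]
        for k in others[rng.random(len(others)) < spec.ii_base_p]:
            pairs.append((pos[int(i)], pos[int(k)]))
            weights.append(1)

    adj = _add_edges(base.adjacency.copy(), pairs, weights)
    conn = base.with_adjacency(adj)
    conn.meta = dict(base.meta, disinhibitory=len(dis_ids))
    return conn, np.sort(dis_ids)


def synth_activity(
    nodes: np.ndarray,
    edge_dims: dict[tuple[int, int], int],
    corr_profile: dict[int, float],
    T: int = 2000,
    seed: int | np.random.Generator = 0,
    on_infeasible: str = "project",
) -> pd.DataFrame:
    """Nonnegative Gaussian-derived traces with edge-dimension-graded pairwise
    correlation.

    A joint Gaussian is drawn whose target correlation between a connected pair
    equals ``corr_profile[max dimension of the connecting edge]`` (dimensions
    missing from the profile interpolate to the nearest lower key; unconnected
    pairs target 0). If the assembled target matrix is not positive
    semidefinite it is either projected onto the PSD cone (``on_infeasible=
    "project"``, with a warning) or an error is raised (``"raise"``). Traces
    are shifted per node to be nonnegative, which leaves Pearson correlations
    unchanged.

    Returns a (T x n_nodes) DataFrame with node ids as columns.
    """
    import warnings

    nodes = np.asarray(nodes)
    if any(not (0.0 <= r < 1.0) for r in corr_profile.values()):
        raise ValueError("profile correlations must be in [0, 1)")
    keys = sorted(corr_profile)
    n = len(nodes)
    node_pos = {int(v): k for k, v in enumerate(nodes)}
    C = np.eye(n)
    for (u, v), dim in edge_dims.items():
        if int(u) not in node_pos or int(v) not in node_pos:
            continue
        lower = [k for k in keys if k <= dim]
        r = corr_profile[lower[-1]] if lower else 0.0
        i, j = node_pos[int(u)], node_pos[int(v)]
        C[i, j] = max(C[i, j] if i != j else 0.0, r) if i != j else 1.0
        if i != j:
            C[j, i] = C[i, j]
    eigval = np.linalg.eigvalsh(C)
    if eigval.min() < -1e-10:
        if on_infeasible == "raise":
            raise ValueError(
                f"target correlation matrix not PSD (min eigenvalue {eigval.min():.3g})"
            )
        warnings.warn("target correlation matrix not PSD; projecting", stacklevel=2)
        w, V = np.linalg.eigh(C)
        C = (V * np.clip(w, 1e-10, None)) @ V.T
        dinv = 1.0 / np.sqrt(np.diag(C))
        C = C * dinv[:, None] * dinv[None, :]
    rng = np.random.default_rng(seed)
    L = np.linalg.cholesky(C + 1e-12 * np.eye(n))
    z = rng.standard_normal((T, n)) @ L.T
    z -= z.min(axis=0, keepdims=True)  # per-node shift: nonnegative, corr-invariant
    return pd.DataFrame(z, columns=[int(v) for v in nodes])
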