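"""Directed flag-complex enumeration and derived simplex statistics.

A directed simplex of dimension ``dim`` is a motif of ``dim + 1`` distinct
neurons admitting a numbering 0..dim (the *position*) such that an edge runs
from every lower- to every higher-numbered member. Position 0 is the *source*,
position ``dim`` the *target*. Reciprocally connected pairs yield one simplex
per valid ordering (standard directed flag complex semantics).

Enumeration proceeds by recursive extension of ordered cliques: a simplex
(v0..vd) extends by every node in the intersection of the out-neighborhoods of
all its members, which guarantees completeness without duplicates.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np

from .core_model import Connectome

__all__ = [
    "SimplexTable",
    "ErBudget",
    "enumerate_simplices",
    "count_simplices",
    "unique_fraction_by_position",
    "node_participation",
    "edge_max_dimension",
    "simplex_core",
    "er_simplex_budget",
    "triad_census",
    "TRIAD_CLASSES",
]

#: the 13 weakly-connected triad isomorphism classes (standard triad-census codes)
TRIAD_CLASSES = (
    "021D", "021U", "021C", "111D", "111U", "030T", "030C",
    "201", "120D", "120U", "120C", "210", "300",
)

#: listing simplices above this dimension requires an explicit opt-in, as the
#: list size can explode combinatorially on dense graphs
DEFAULT_LIST_DIM_GUARD = 10


@dataclass
class SimplexTable:
    """Per-dimension arrays of ordered node tuples.

    ``by_dim[d]`` is an ``(S_d, d+1)`` integer array of neuron ids with
    position 0 = source and position d = target. Dimension 0 is the node list,
    dimension 1 the edge list.
    """

    by_dim: dict[int, np.ndarray]

    @property
    def max_dim(self) -> int:
        dims = [d for d, arr in self.by_dim.items() if len(arr)]
        return max(dims) if dims else -1

    def counts(self) -> dict[int, int]:
        return {d: int(len(arr)) for d, arr in sorted(self.by_dim.items())}

    def simplices(self, dim: int) -> np.ndarray:
        return self.by_dim.get(dim, np.empty((0, dim + 1), dtype=np.int64))

    def n_simplices(self, dim: int) -> int:
        return int(len(self.simplices(dim)))


def _extend_count(nbrs, cand, depth, max_depth, counts):
    """Count extensions of the current clique; cand = intersection of member
    out-neighborhoods (sorted positional indices)."""
    counts[depth] += len(cand)
    if depth == max_depth:
        return
    for w in cand:
        sub = np.intersect1d(cand, nbrs[w], assume_unique=True)
        if len(sub):
            _extend_count(nbrs, sub, depth + 1, max_depth, counts)


def _extend_list(nbrs, verts, cand, max_depth, out):
    for w in cand:
        new = verts + (int(w),)
        out[len(new) - 1].append(new)
        if len(new) - 1 < max_depth:
            sub = np.intersect1d(cand, nbrs[w], assume_unique=True)
            if len(sub):
                _extend_list(nbrs, new, sub, max_depth, out)


def enumerate_simplices(
    graph: Connectome, max_dim: int | None = None, allow_large: bool = False
) -> SimplexTable:
    """List all directed simplices of ``graph`` up to ``max_dim``.

    The graph must be simple and self-loop free (guaranteed by
    :class:`~simplicia.core_model.Connectome`). With ``max_dim=None``
    enumeration continues until a dimension is empty. Listing above dimension
    10 requires ``allow_large=True``.
    """
    if max_dim is not None and max_dim > DEFAULT_LIST_DIM_GUARD and not allow_large:
        raise ValueError(
            f"listing simplices above dim {DEFAULT_LIST_DIM_GUARD} requires "
            "allow_large=True"
        )
    n = graph.n_nodes
    ids = graph.node_ids
    a = graph.adjacency
    nbrs = [a.indices[a.indptr[i]:a.indptr[i + 1]] for i in range(n)]
    cap = max_dim if max_dim is not None else n
    coo = a.tocoo()
    out: dict[int, list[tuple[int, ...]]] = {d: [] for d in range(2, cap + 1)}
    if cap >= 2:
        for u, v in zip(coo.row, coo.col):
            cand = np.intersect1d(nbrs[u], nbrs[v], assume_unique=True)
            if len(cand):
                _extend_list(nbrs, (int(u), int(v)), cand, cap, out)

    by_dim: dict[int, np.ndarray] = {0: ids.reshape(-1, 1).astype(np.int64)}
    if cap >= 1:
        if a.nnz:
            by_dim[1] = ids[np.column_stack([coo.row, coo.col])]
        else:
            by_dim[1] = np.empty((0, 2), dtype=np.int64)
    for d in range(2, cap + 1):
        tuples = out.get(d, [])
        if tuples:
            by_dim[d] = ids[np.asarray(tuples, dtype=np.int64)]
        elif max_dim is not None:
            by_dim[d] = np.empty((0, d + 1), dtype=np.int64)
        else:
            break
    return SimplexTable(by_dim=by_dim)


def count_simplices(graph: Connectome, max_dim: int | None = None) -> dict[int, int]:
    """Per-dimension simplex counts without materializing the lists.

    Equivalent to ``enumerate_simplices(...).counts()`` but memory-light, which
    matters on large sparse graphs.
    """
    n = graph.n_nodes
    a = graph.adjacency
    nbrs = [a.indices[a.indptr[i]:a.indptr[i + 1]] for i in range(n)]
    cap = max_dim if max_dim is not None else n
    counts = np.zeros(cap + 1, dtype=np.int64)
    counts[0] = n
    if cap >= 1:
        counts[1] = a.nnz
    if cap >= 2 and a.nnz:
        coo = a.tocoo()
        for u, v in zip(coo.row, coo.col):
            cand = np.intersect1d(nbrs[u], nbrs[v], assume_unique=True)
            if len(cand):
                _extend_count(nbrs, cand, 2, cap, counts)
    result = {}
    for d in range(cap + 1):
        if counts[d] == 0 and d > 1 and max_dim is None:
            break
        result[d] = int(counts[d])
    return result


# ---------------------------------------------------------------------------
# derived statistics
# ---------------------------------------------------------------------------

def unique_fraction_by_position(
    table: SimplexTable, dim: int
) -> tuple[np.ndarray, np.ndarray]:
    """Fraction of unique neurons per simplex position, and the profile
    normalized to the fraction at the source position.

    ``fraction[pos] = |unique nodes at pos| / S_dim``. A rising normalized
    profile from source to target signals divergent feed-forward flow: few
    distinct sources fanning out onto many distinct targets.
    """
    simp = table.simplices(dim)
    if len(simp) == 0:
        nan = np.full(dim + 1, np.nan)
        return nan, nan.copy()
    s = len(simp)
    fraction = np.array(
        [len(np.unique(simp[:, p])) / s for p in range(dim + 1)], dtype=float
    )
    normalized = fraction / fraction[0]
    return fraction, normalized


def node_participation(table: SimplexTable) -> dict[int, dict[int, dict[int, int]]]:
    """``Par[dim][pos][node]`` = number of dim-simplices containing ``node`` at
    position ``pos``. Only nonzero entries are stored."""
    par: dict[int, dict[int, dict[int, int]]] = {}
    for dim, simp in table.by_dim.items():
        if dim < 1 or len(simp) == 0:
            continue
        par[dim] = {}
        for pos in range(dim + 1):
            nodes, counts = np.unique(simp[:, pos], return_counts=True)
            par[dim][pos] = dict(zip(nodes.tolist(), counts.tolist()))
    return par


def edge_max_dimension(
    table: SimplexTable, graph: Connectome
) -> dict[tuple[int, int], int]:
    """``D[(u, v)]`` = maximal dimension over simplices in which ``u`` sits at a
    lower position than ``v``. Every edge participates in at least the
    1-simplex it forms, so D >= 1 for all edges."""
    pre, post, _ = graph.edges()
    dmap = {(int(u), int(v)): 1 for u, v in zip(pre, post)}
    for dim in sorted(d for d in table.by_dim if d >= 2):
        simp = table.by_dim[dim]
        for row in simp:
            for i in range(dim + 1):
                for j in range(i + 1, dim + 1):
                    key = (int(row[i]), int(row[j]))
                    if key in dmap and dmap[key] < dim:
                        dmap[key] = dim
    return dmap


def simplex_core(table: SimplexTable, dim: int) -> set[int]:
    """The set of nodes participating in at least one ``dim``-simplex (the
    network's "dim-core" in the simplicial sense)."""
    simp = table.simplices(dim)
    return set() if len(simp) == 0 else set(np.unique(simp).tolist())


# ---------------------------------------------------------------------------
# reconstruction-error control
# ---------------------------------------------------------------------------

@dataclass
class ErBudget:
    """Edge budget for an Erdos-Renyi explanation of high-dimensional simplices.

    In an undirected ER graph on ``n`` nodes with connection probability ``p``
    the expected maximal simplex dimension is ~ -2 log(n)/log(p). Solving for
    the ``p`` needed to reach ``target_dim`` gives the directed edge count
    ``n (n-1) p`` such a graph would need; ``removal_fraction`` is the share of
    those edges that a reconstruction would have to miss to arrive at the
    observed count. ``survival_probability(recall)`` is the chance that one
    specific target_dim-simplex keeps all of its C(target_dim+1, 2) edges under
    independent edge recall.
    """

    n: int
    target_dim: int
    p: float
    required_directed_edges: float
    observed_edges: int
    removal_fraction: float
    recall: float | None = None
    survival_probability: float | None = None


def er_simplex_budget(
    n: int, target_dim: int, observed_edges: int, recall: float | None = None
) -> ErBudget:
    """Quantify how implausibly dense an ER graph must be to contain a
    ``target_dim``-simplex, versus the observed edge count."""
    if n < 2:
        raise ValueError("need n >= 2")
    if target_dim < 1:
        raise ValueError("need target_dim >= 1")
    if observed_edges < 0:
        raise ValueError("observed_edges must be >= 0")
    # target_dim = -2 ln(n) / ln(p)  =>  p = n^(-2/target_dim)
    p = float(n ** (-2.0 / target_dim))
    if p >= 1:
        raise ValueError("solved connection probability >= 1; n too small")
    required = n * (n - 1) * p
    removal = 1.0 - observed_edges / required
    removal = float(min(max(removal, 0.0), 1.0))
    survival = None
    if recall is not None:
        n_edges_in_simplex = math.comb(target_dim + 1, 2)
        survival = float(recall ** n_edges_in_simplex)
    return ErBudget(
        n=n, target_dim=target_dim, p=p, required_directed_edges=required,
        observed_edges=observed_edges, removal_fraction=removal,
        recall=recall, survival_probability=survival,
    )


# ---------------------------------------------------------------------------
# triad census
# ---------------------------------------------------------------------------

def _connected_triads(graph: Connectome) -> np.ndarray:
    """All weakly-connected node triples (positional indices), each once."""
    a = graph.adjacency
    sym = ((a + a.T) > 0).tocsr()
    n = graph.n_nodes
    und = [sym.indices[sym.indptr[i]:sym.indptr[i + 1]] for i in range(n)]
    triads = set()
    rows, cols = sym.nonzero()
    for u, v in zip(rows, cols):
        if u >= v:
            continue
        for w in np.union1d(und[u], und[v]):
            if w == u or w == v:
                continue
            triads.add(tuple(sorted((int(u), int(v), int(w)))))
    if not triads:
        return np.empty((0, 3), dtype=np.int64)
    return np.array(sorted(triads), dtype=np.int64)


def _triad_code(adj_bool: np.ndarray) -> str:
    """Classify a 3-node directed graph into its standard triad-census code."""
    import networkx as nx

    g = nx.DiGraph()
    g.add_nodes_from(range(3))
    for i in range(3):
        for j in range(3):
            if i != j and adj_bool[i, j]:
                g.add_edge(i, j)
    return nx.triad_type(g)


def triad_census(
    graph: Connectome, n_samples: int = 100_000, seed: int | np.random.Generator = 0
) -> dict[str, float]:
    """Estimated counts of the 13 connected-triad classes.

    Connected triples are enumerated exactly; when their number exceeds
    ``n_samples`` a uniform sample is classified and class frequencies are
    scaled linearly by the exact total, otherwise the census is exact.
    """
    rng = np.random.default_rng(seed)
    triads = _connected_triads(graph)
    total = len(triads)
    census = {c: 0.0 for c in TRIAD_CLASSES}
    if total == 0:
        return census
    if total > n_samples:
        pick = rng.choice(total, size=n_samples, replace=False)
        sample = triads[pick]
        scale = total / n_samples
    else:
        sample = triads
        scale = 1.0
    dense = graph.adjacency.toarray() > 0
    for (u, v, w) in sample:
        code = _triad_code(dense[np.ix_([u, v, w], [u, v, w])])
        if code in census:
            census[code] += scale
        else:  # pragma: no cover - only reachable on disconnected triples
            warnings.warn(f"unexpected disconnected triad code {code}", stacklevel=2)
    return census
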