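"""Statistics relating inhibitory neurons to excitatory directed simplices.

The central objects are two simplex x position x interneuron synapse-count
tensors: M_ei (synapses from the excitatory neuron at position j of simplex i
onto interneuron k) and M_ie (synapses from interneuron k onto that neuron).
Summing over position gives simplex x interneuron matrices M'_ei and M'_ie;
their product I = M'_ei @ M'_ie.T counts synapse-weighted E->I->E paths and is
the matrix of disynaptic inhibition between simplices. Everything else in this
module — position profiles, symmetry, overlap correlations, targeting and
disinhibition tests — is a reduction of, or companion to, those objects.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.sparse as sp
from scipy.stats import hypergeom, pearsonr

from .core_model import Connectome
from .simplices import SimplexTable

__all__ = [
    "InhibitionTensors",
    "TargetingTestResult",
    "inhibition_tensors",
    "inhibitory_degree_by_position",
    "aggregate_profiles",
    "disynaptic_inhibition",
    "symmetry_score",
    "overlap_matrix",
    "overlap_inhibition_correlation",
    "inhibitory_targeting_test",
    "simplex_degrees_of_inhibitory",
    "disinhibition_profile",
    "position_profile_stratified",
    "synapses_per_connection_by_position",
]


@dataclass
class InhibitionTensors:
    """Simplex x position x interneuron synapse-count tensors, stored as sparse
    (S * (dim+1)) x N_inh matrices in simplex-major order, plus their
    position-summed reductions."""

    dim: int
    n_simplices: int
    inh_ids: np.ndarray
    m_ei: sp.csr_matrix        # row i*(dim+1)+j  ->  synapses pos-j-of-i -> interneuron
    m_ie: sp.csr_matrix        # row i*(dim+1)+j  ->  synapses interneuron -> pos-j-of-i
    m_ei_reduced: sp.csr_matrix  # S x N_inh
    m_ie_reduced: sp.csr_matrix

    def slab(self, which: str, simplex: int) -> np.ndarray:
        """Dense (dim+1) x N_inh slab of one simplex."""
        m = self.m_ei if which == "ei" else self.m_ie
        lo = simplex * (self.dim + 1)
        return m[lo:lo + self.dim + 1].toarray()


def _position_reducer(n_simplices: int, dim: int) -> sp.csr_matrix:
    rows = np.repeat(np.arange(n_simplices), dim + 1)
    cols = np.arange(n_simplices * (dim + 1))
    data = np.ones_like(cols)
    return sp.csr_matrix((data, (rows, cols)),
                         shape=(n_simplices, n_simplices * (dim + 1)))


def inhibition_tensors(
    table: SimplexTable, dim: int, conn: Connectome
) -> InhibitionTensors:
    """Build M_ei / M_ie and their position-summed reductions for one dimension."""
    simp = table.simplices(dim)
    if len(simp) == 0:
        raise ValueError(f"no simplices of dimension {dim}")
    i_mask = conn.class_mask("I")
    inh_ids = conn.node_ids[i_mask]
    if len(inh_ids) == 0:
        raise ValueError("connectome has no inhibitory neurons")
    i_pos = np.flatnonzero(i_mask)
    flat_nodes = conn.ids_to_pos(simp.ravel())
    a_ei = sp.csr_matrix(conn.adjacency[:, i_pos])      # n x N_inh
    a_ie = sp.csr_matrix(conn.adjacency[i_pos, :].T)    # n x N_inh (transposed I->*)
    m_ei = sp.csr_matrix(a_ei[flat_nodes])
    m_ie = sp.csr_matrix(a_ie[flat_nodes])
    red = _position_reducer(len(simp), dim)
    return InhibitionTensors(
        dim=dim, n_simplices=len(simp), inh_ids=inh_ids,
        m_ei=m_ei, m_ie=m_ie,
        m_ei_reduced=sp.csr_matrix(red @ m_ei),
        m_ie_reduced=sp.csr_matrix(red @ m_ie),
    )


def inhibitory_degree_by_position(
    conn: Connectome, table: SimplexTable, dim: int
) -> pd.DataFrame:
    """Mean number of distinct inhibitory partners of the neuron at each
    simplex position (binarized connections, averaged over simplices).

    ``in`` counts interneurons innervating the neuron at that position,
    ``out`` interneurons it innervates. For dim = 1 this is the two-point
    source/target profile of individual connections.
    """
    simp = table.simplices(dim)
    if len(simp) == 0:
        return pd.DataFrame({"position": [], "in": [], "out": []})
    i_pos = np.flatnonzero(conn.class_mask("I"))
    inh_in = np.asarray((conn.adjacency[i_pos] > 0).sum(axis=0)).ravel()
    inh_out = np.asarray((conn.adjacency[:, i_pos] > 0).sum(axis=1)).ravel()
    node_pos = conn.ids_to_pos(simp.ravel()).reshape(simp.shape)
    return pd.DataFrame({
        "position": np.arange(dim + 1),
        "in": inh_in[node_pos].mean(axis=0),
        "out": inh_out[node_pos].mean(axis=0),
    })


def aggregate_profiles(profiles: list[np.ndarray]) -> tuple[np.ndarray, np.ndarray]:
    """Mean and SD over subnetworks of per-position profiles."""
    stack = np.vstack(profiles)
    return stack.mean(axis=0), stack.std(axis=0)


def disynaptic_inhibition(
    tensors: InhibitionTensors, binarize: bool = False
) -> np.ndarray:
    """Simplex x simplex matrix of disynaptic inhibition I = M'_ei @ M'_ie.T.

    Entry (i, j) is the synapse-weighted count of E->I->E paths leaving simplex
    i and entering simplex j. ``binarize=True`` counts interneuron-mediated
    paths with connections reduced to 0/1 instead of synapse counts.
    """
    ei = tensors.m_ei_reduced
    ie = tensors.m_ie_reduced
    if binarize:
        ei = (ei > 0).astype(np.int64)
        ie = (ie > 0).astype(np.int64)
    return np.asarray((ei @ ie.T).todense(), dtype=np.int64)


def symmetry_score(I: np.ndarray) -> float:
    """Normalized antisymmetry variance S = var(I - I.T) / var(I).

    Population variances over off-diagonal entries only: the diagonal of
    I - I.T is identically zero and the diagonal of I measures self-inhibition,
    not between-simplex inhibition. S = 0 for a perfectly symmetric matrix and
    has expectation 2 when entries (i, j) and (j, i) are independent.
    """
    I = np.asarray(I, dtype=float)
    if I.ndim != 2 or I.shape[0] != I.shape[1] or I.shape[0] < 2:
        raise ValueError("need a square matrix of size >= 2")
    off = ~np.eye(I.shape[0], dtype=bool)
    denom = I[off].var()
    if denom == 0:
        warnings.warn("var(I) over off-diagonal entries is 0", stacklevel=2)
        return float("nan")
    return float((I - I.T)[off].var() / denom)


def overlap_matrix(
    table: SimplexTable, dim: int, j: int = 0, k: int | None = None
) -> np.ndarray:
    """O[s, t] = number of shared neurons between simplices s and t within
    positions j..k (order-agnostic within the range; k defaults to dim)."""
    if k is None:
        k = dim
    if not (0 <= j <= k <= dim):
        raise ValueError("need 0 <= j <= k <= dim")
    simp = table.simplices(dim)
    if len(simp) == 0:
        return np.zeros((0, 0), dtype=np.int64)
    sub = simp[:, j:k + 1]
    nodes = np.unique(sub)
    lookup = {int(v): c for c, v in enumerate(nodes)}
    rows = np.repeat(np.arange(len(sub)), sub.shape[1])
    cols = np.array([lookup[int(v)] for v in sub.ravel()])
    B = sp.csr_matrix(
        (np.ones(len(rows), dtype=np.int64), (rows, cols)),
        shape=(len(sub), len(nodes)),
    )
    return np.asarray((B @ B.T).todense(), dtype=np.int64)


def _offdiag_flat(M: np.ndarray) -> np.ndarray:
    M = np.asarray(M, dtype=float)
    off = ~np.eye(M.shape[0], dtype=bool)
    return M[off]


def overlap_inhibition_correlation(
    o_source: np.ndarray, o_target: np.ndarray, I: np.ndarray
) -> dict[str, float]:
    """Pearson correlations, over off-diagonal simplex pairs, between source-
    side overlap, target-side overlap, and disynaptic inhibition."""
    xs = _offdiag_flat(o_source)
    xt = _offdiag_flat(o_target)
    xi = _offdiag_flat(I)
    out = {}
    for name, (u, v) in {
        "source_inhibition": (xs, xi),
        "target_inhibition": (xt, xi),
        "source_target": (xs, xt),
    }.items():
        if u.std() == 0 or v.std() == 0:
            warnings.warn(f"constant input for correlation {name}", stacklevel=2)
            out[name] = float("nan")
        else:
            out[name] = float(pearsonr(u, v).statistic)
    return out


@dataclass
class TargetingTestResult:
    """Per-interneuron inhibitory-targeting test against a pooled
    hypergeometric null."""

    table: pd.DataFrame  # neuron_id, d_ttl, d_inh, p_value, flagged
    threshold: float
    pool_total: int
    pool_inhibitory: int

    @property
    def flagged_ids(self) -> np.ndarray:
        return self.table.loc[self.table["flagged"], "neuron_id"].to_numpy()

    @property
    def flagged_fraction(self) -> float:
        return float(self.table["flagged"].mean())


def inhibitory_targeting_test(
    conn: Connectome, threshold: float = 1e-6
) -> TargetingTestResult:
    """Flag interneurons whose outdegree onto other interneurons exceeds a
    pooled hypergeometric null.

    The null keeps each interneuron's total outdegree d_ttl and the overall
    fraction of inhibitory targets: neuron j's d_ttl targets are drawn without
    replacement from the pooled sum of all interneurons' target slots, of which
    the pooled inhibitory outdegree are "successes". p_j is the survival
    probability of observing >= d_inh inhibitory targets; d_inh = 0 gives
    p_j = 1.
    """
    i_mask = conn.class_mask("I")
    i_pos = np.flatnonzero(i_mask)
    if len(i_pos) == 0:
        raise ValueError("connectome has no inhibitory neurons")
    a_bin = conn.adjacency > 0
    d_ttl = np.asarray(a_bin[i_pos].sum(axis=1)).ravel()
    d_inh = np.asarray(a_bin[i_pos][:, i_pos].sum(axis=1)).ravel()
    M = int(d_ttl.sum())
    N = int(d_inh.sum())
    if M == 0:
        raise ValueError("inhibitory population has no outgoing edges")
    p = hypergeom.sf(d_inh - 1, M, N, d_ttl)
    df = pd.DataFrame({
        "neuron_id": conn.node_ids[i_pos],
        "d_ttl": d_ttl,
        "d_inh": d_inh,
        "p_value": p,
        "flagged": p <= threshold,
    })
    return TargetingTestResult(df, threshold, M, N)


def simplex_degrees_of_inhibitory(
    conn: Connectome,
    table: SimplexTable,
    dim: int,
    source_positions: tuple[int, ...] = (0, 1, 2),
    target_positions: tuple[int, ...] = (4, 5, 6),
) -> pd.DataFrame:
    """Per-interneuron simplex in/out-degrees.

    ``simplex_indegree`` counts connections from excitatory neurons sitting at
    a source position of a dim-simplex onto the interneuron; a neuron occupying
    the same position in several simplices contributes once per simplex
    occurrence. ``simplex_outdegree`` counts connections from the interneuron
    onto neurons at target positions, with the same multiplicity rule.
    """
    simp = table.simplices(dim)
    i_pos = np.flatnonzero(conn.class_mask("I"))
    inh_ids = conn.node_ids[i_pos]
    indeg = np.zeros(len(i_pos), dtype=np.int64)
    outdeg = np.zeros(len(i_pos), dtype=np.int64)
    if len(simp):
        a_bin = (conn.adjacency > 0).astype(np.int64)
        to_i = sp.csr_matrix(a_bin[:, i_pos])    # n x N_inh
        from_i = sp.csr_matrix(a_bin[i_pos, :].T)  # n x N_inh
        node_pos = conn.ids_to_pos(simp.ravel()).reshape(simp.shape)
        for p in source_positions:
            if p <= dim:
                indeg += np.asarray(to_i[node_pos[:, p]].sum(axis=0)).ravel()
        for p in target_positions:
            if p <= dim:
                outdeg += np.asarray(from_i[node_pos[:, p]].sum(axis=0)).ravel()
    return pd.DataFrame({
        "neuron_id": inh_ids,
        "simplex_indegree": indeg,
        "simplex_outdegree": outdeg,
    })


def disinhibition_profile(
    conn: Connectome,
    targeting: TargetingTestResult,
    simplex_degrees: pd.DataFrame,
    degree_column: str = "simplex_indegree",
    bins: int | np.ndarray = 5,
) -> pd.DataFrame:
    """Inhibitory indegree of interneurons split by whether it comes from
    targeting-flagged (disinhibitory candidate) or non-targeting interneurons,
    per simplex-degree bin.

    Returns per-bin mean absolute indegrees and the normalized share
    contributed by flagged neurons.
    """
    i_pos = np.flatnonzero(conn.class_mask("I"))
    inh_ids = conn.node_ids[i_pos]
    flagged = np.isin(inh_ids, targeting.flagged_ids)
    a_bin = (conn.adjacency > 0).astype(np.int64)
    ii = np.asarray(sp.csr_matrix(a_bin[i_pos][:, i_pos]).todense())
    indeg_flagged = ii[flagged].sum(axis=0)
    indeg_plain = ii[~flagged].sum(axis=0)
    deg = simplex_degrees.set_index("neuron_id").loc[inh_ids, degree_column].to_numpy()
    edges = (np.histogram_bin_edges(deg, bins=bins)
             if np.isscalar(bins) else np.asarray(bins, dtype=float))
    which = np.clip(np.digitize(deg, edges) - 1, 0, len(edges) - 2)
    rows = []
    for b in range(len(edges) - 1):
        sel = which == b
        if not sel.any():
            rows.append((edges[b], edges[b + 1], 0, np.nan, np.nan, np.nan))
            continue
        mf = indeg_flagged[sel].mean()
        mp = indeg_plain[sel].mean()
        share = mf / (mf + mp) if (mf + mp) > 0 else np.nan
        rows.append((edges[b], edges[b + 1], int(sel.sum()), mf, mp, share))
    return pd.DataFrame(
        rows,
        columns=["bin_lo", "bin_hi", "n_neurons", "indegree_targeting",
                 "indegree_other", "targeting_share"],
    )


def position_profile_stratified(
    conn: Connectome,
    table: SimplexTable,
    dim: int,
    class_labels: pd.Series,
    direction: str = "onto_simplex",
    normalize_to_source: bool = False,
) -> pd.DataFrame:
    """Per-(position, class) connection probability with simplex nodes.

    ``class_labels`` maps neuron id -> stratum (e.g. proofreading status or
    interneuron subtype). For ``direction="onto_simplex"`` the value at
    (pos, cls) is the probability that a class member innervates the neuron at
    that position (mean count over simplices divided by class size); for
    ``"from_simplex"`` the direction is reversed. Empty classes yield NaN with
    a warning. ``normalize_to_source`` divides each class profile by its value
    at position 0.
    """
    if direction not in ("onto_simplex", "from_simplex"):
        raise ValueError("direction must be 'onto_simplex' or 'from_simplex'")
    simp = table.simplices(dim)
    if len(simp) == 0:
        raise ValueError(f"no simplices of dimension {dim}")
    node_pos = conn.ids_to_pos(simp.ravel()).reshape(simp.shape)
    a_bin = (conn.adjacency > 0).astype(np.int64)
    out = {}
    for cls in sorted(class_labels.unique()):
        member_ids = class_labels.index[class_labels == cls]
        member_ids = member_ids[np.isin(member_ids, conn.node_ids)]
        if len(member_ids) == 0:
            warnings.warn(f"empty class {cls!r}", stacklevel=2)
            out[cls] = np.full(dim + 1, np.nan)
            continue
        members = conn.ids_to_pos(member_ids)
        if direction == "onto_simplex":
            counts = np.asarray(a_bin[members].sum(axis=0)).ravel()
        else:
            counts = np.asarray(a_bin[:, members].sum(axis=1)).ravel()
        prof = counts[node_pos].mean(axis=0) / len(members)
        if normalize_to_source:
            prof = prof / prof[0] if prof[0] > 0 else np.full(dim + 1, np.nan)
        out[cls] = prof
    df = pd.DataFrame(out)
    df.insert(0, "position", np.arange(dim + 1))
    return df


def synapses_per_connection_by_position(
    conn: Connectome, table: SimplexTable, dim: int
) -> pd.DataFrame:
    """Mean synapse count per existing connection between the simplex neuron at
    each position and the inhibitory population, separately for E->I and I->E."""
    simp = table.simplices(dim)
    if len(simp) == 0:
        raise ValueError(f"no simplices of dimension {dim}")
    i_pos = np.flatnonzero(conn.class_mask("I"))
    node_pos = conn.ids_to_pos(simp.ravel()).reshape(simp.shape)
    a = conn.adjacency
    ei_mean = np.full(dim + 1, np.nan)
    ie_mean = np.full(dim + 1, np.nan)
    for p in range(dim + 1):
        nodes = node_pos[:, p]
        ei = sp.csr_matrix(a[nodes][:, i_pos])
        ie = sp.csr_matrix(a[i_pos][:, nodes])
        if ei.nnz:
            ei_mean[p] = ei.data.mean()
        if ie.nnz:
            ie_mean[p] = ie.data.mean()
    return pd.DataFrame({
        "position": np.arange(dim + 1), "ei": ei_mean, "ie": ie_mean,
    })
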