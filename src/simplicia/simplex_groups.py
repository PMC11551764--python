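"""Louvain grouping of simplices by source-/target-side overlap and the reduced
group-level excitation/inhibition network.

Clustering the source-side overlap matrix yields *source groups* (simplices
sharing input neurons), clustering the target-side overlap matrix *target
groups*. The reduced network then summarizes, for every (source group, target
group) pair, the mean any-position overlap (excitation) and the fraction of
simplex pairs whose disynaptic inhibition exceeds the 95th percentile of the
column-shuffle control (inhibition).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd

__all__ = ["GroupAssignment", "GroupNetwork", "cluster_simplices",
           "group_network", "group_sizes"]


@dataclass
class GroupAssignment:
    """Per-simplex integer group labels (contiguous from 0)."""

    labels: np.ndarray
    flavor: str          # "source" or "target"
    resolution: float

    @property
    def n_groups(self) -> int:
        return int(self.labels.max()) + 1 if len(self.labels) else 0

    def members(self, group: int) -> np.ndarray:
        return np.flatnonzero(self.labels == group)


@dataclass
class GroupNetwork:
    """Reduced group-level network: excitation = mean any-position overlap,
    inhibition = fraction of pairs with above-control disynaptic inhibition."""

    excitation: np.ndarray   # source groups x target groups
    inhibition: np.ndarray
    source_sizes: np.ndarray
    target_sizes: np.ndarray


def cluster_simplices(
    O: np.ndarray,
    resolution: float = 2.2,
    seed: int = 0,
    flavor: str = "source",
    n_restarts: int = 1,
) -> GroupAssignment:
    """Louvain partition of simplices on the weighted overlap graph.

    The adjacency is ``O`` with its diagonal zeroed (self-overlap is not
    affinity). Deterministic under ``seed``; with ``n_restarts`` > 1 the
    best-modularity partition over restarts is kept. An all-zero matrix puts
    every simplex in its own group, with a warning.
    """
    O = np.asarray(O, dtype=float)
    n = O.shape[0]
    if n == 0:
        return GroupAssignment(np.array([], dtype=np.int64), flavor, resolution)
    W = O.copy()
    np.fill_diagonal(W, 0.0)
    if not W.any():
        warnings.warn("all-zero overlap matrix: every simplex its own group",
                      stacklevel=2)
        return GroupAssignment(np.arange(n, dtype=np.int64), flavor, resolution)
    g = nx.from_numpy_array(W)  # undirected weighted graph
    best, best_q = None, -np.inf
    for r in range(max(1, n_restarts)):
        comms = nx.community.louvain_communities(
            g, weight="weight", resolution=resolution, seed=seed + r
        )
        q = nx.community.modularity(g, comms, weight="weight",
                                    resolution=resolution)
        if q > best_q:
            best, best_q = comms, q
    labels = np.empty(n, dtype=np.int64)
    # relabel contiguously, ordered by smallest member for determinism
    for new, comm in enumerate(sorted(best, key=min)):
        labels[sorted(comm)] = new
    return GroupAssignment(labels, flavor, resolution)


def group_network(
    src_groups: GroupAssignment,
    tgt_groups: GroupAssignment,
    O_any: np.ndarray,
    I: np.ndarray,
    shuffled_Is: list[np.ndarray],
    percentile: float = 95.0,
    pooled_percentile: bool = False,
) -> GroupNetwork:
    """Group-level excitation and inhibition matrices.

    ``excitation[g, h]`` is the mean any-position overlap over ordered pairs
    (s in source group g, t in target group h, s != t). ``inhibition[g, h]`` is
    the fraction of those pairs whose I[s, t] strictly exceeds the per-pair
    95th percentile over the shuffle ensemble (or, with
    ``pooled_percentile=True``, the pooled percentile over all off-diagonal
    shuffled entries — useful for small shuffle budgets). Empty pair sets give
    NaN.
    """
    if len(shuffled_Is) < 1:
        raise ValueError("need at least one shuffled control")
    stack = np.stack(shuffled_Is).astype(float)
    if pooled_percentile:
        off = ~np.eye(I.shape[0], dtype=bool)
        thresh = np.full(I.shape, np.percentile(stack[:, off], percentile))
    else:
        thresh = np.percentile(stack, percentile, axis=0)
    above = np.asarray(I, dtype=float) > thresh

    ns, nt = src_groups.n_groups, tgt_groups.n_groups
    excitation = np.full((ns, nt), np.nan)
    inhibition = np.full((ns, nt), np.nan)
    O_any = np.asarray(O_any, dtype=float)
    for g in range(ns):
        sg = src_groups.members(g)
        for h in range(nt):
            th = tgt_groups.members(h)
            pairs_s = np.repeat(sg, len(th))
            pairs_t = np.tile(th, len(sg))
            keep = pairs_s != pairs_t
            if not keep.any():
                continue
            excitation[g, h] = O_any[pairs_s[keep], pairs_t[keep]].mean()
            inhibition[g, h] = above[pairs_s[keep], pairs_t[keep]].mean()
    return GroupNetwork(
        excitation=excitation,
        inhibition=inhibition,
        source_sizes=np.bincount(src_groups.labels, minlength=ns),
        target_sizes=np.bincount(tgt_groups.labels, minlength=nt),
    )


def group_sizes(assignment: GroupAssignment,
                log_bins: int | None = None) -> pd.DataFrame:
    """Group size distribution; with ``log_bins`` a log-spaced histogram is
    returned instead of the raw tally."""
    sizes = np.bincount(assignment.labels, minlength=assignment.n_groups)
    if log_bins is None:
        return pd.DataFrame({"group": np.arange(len(sizes)), "size": sizes})
    edges = np.geomspace(1, max(sizes.max(), 2), log_bins + 1)
    hist, _ = np.histogram(sizes, bins=edges)
    return pd.DataFrame({"bin_lo": edges[:-1], "bin_hi": edges[1:], "count": hist})
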