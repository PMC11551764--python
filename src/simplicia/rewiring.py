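"""Plasticity-inspired structural rewiring.

A rewiring step removes ``m`` edges confined to low simplex dimensions
(maximal participation dimension <= D) and adds ``m`` edges between currently
unconnected ordered pairs, with addition probability proportional to

    P(a -> b)  ~  sum_{dim > D}  sum_{i < j in pos}  Par[dim, i](a) * Par[dim, j](b)

where Par[dim, pos](a) is the number of dim-simplices containing ``a`` at
position ``pos``. With pos = {0, 1} (the default) new edges preferentially
join neurons that act as sources of many high-dimensional simplices, which
strengthens the divergent feed-forward backbone. Both Par and the edge
dimensions are computed once on the pre-step graph; the total edge count is
conserved exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.sparse as sp

from .core_model import Connectome
from .simplices import (SimplexTable, count_simplices, edge_max_dimension,
                        enumerate_simplices, node_participation)

__all__ = ["RewiringConfig", "rewiring_step", "rewiring_schedule"]


@dataclass
class RewiringConfig:
    """Schedule of (D, m) rewiring steps with eligible position set ``pos``."""

    schedule: list[tuple[int, int]] = field(
        default_factory=lambda: [(3, 2000)] + [(2, 10000)] * 3
    )
    pos: tuple[int, ...] = (0, 1)
    seed: int = 0
    max_dim: int | None = None  # cap for simplex enumeration per step

    def __post_init__(self):
        if not self.schedule:
            raise ValueError("schedule must be nonempty")
        for D, m in self.schedule:
            if m < 0:
                raise ValueError("m must be >= 0")


def _addition_probability(
    graph: Connectome, table: SimplexTable, D: int, pos: tuple[int, ...]
) -> np.ndarray:
    """Unnormalized dense addition-probability matrix on positional indices."""
    n = graph.n_nodes
    par = node_participation(table)
    P = np.zeros((n, n), dtype=float)
    id_to_pos = {int(v): k for k, v in enumerate(graph.node_ids)}
    for dim, by_pos in par.items():
        if dim <= D:
            continue
        for i in pos:
            for j in pos:
                if not (i < j and i <= dim and j <= dim):
                    continue
                wa = np.zeros(n)
                wb = np.zeros(n)
                for node, c in by_pos.get(i, {}).items():
                    wa[id_to_pos[int(node)]] = c
                for node, c in by_pos.get(j, {}).items():
                    wb[id_to_pos[int(node)]] = c
                P += np.outer(wa, wb)
    return P


def rewiring_step(
    graph: Connectome,
    D: int,
    m: int,
    pos: tuple[int, ...] = (0, 1),
    seed: int | np.random.Generator = 0,
    table: SimplexTable | None = None,
    max_dim: int | None = None,
) -> tuple[Connectome, pd.DataFrame]:
    """One rewiring step: remove ``m`` low-dimension edges, add ``m`` new ones.

    Removal picks uniformly at random among edges whose maximal simplex
    dimension is <= D; addition samples without replacement (sequential draws
    with renormalization) among ordered pairs unconnected after removal —
    including pairs just vacated — with the participation-product probability.
    Par and edge dimensions come from the pre-step graph. Errors if fewer than
    ``m`` edges are eligible or the addition probability mass is all zero.

    Returns the rewired connectome and a change log (step-local) with one row
    per removed/added edge.
    """
    rng = np.random.default_rng(seed)
    if table is None:
        table = enumerate_simplices(graph, max_dim=max_dim)
    log_rows: list[tuple[str, int, int]] = []
    if m == 0:
        return graph.with_adjacency(graph.adjacency.copy()), pd.DataFrame(
            log_rows, columns=["action", "pre_id", "post_id"])

    dmap = edge_max_dimension(table, graph)
    eligible = [e for e, d in dmap.items() if d <= D]
    if len(eligible) < m:
        raise ValueError(
            f"only {len(eligible)} edges with max dimension <= {D}; need {m}"
        )
    pick = rng.choice(len(eligible), size=m, replace=False)
    removed = [eligible[int(k)] for k in pick]

    lil = graph.adjacency.tolil()
    id_to_pos = {int(v): k for k, v in enumerate(graph.node_ids)}
    for (u, v) in removed:
        lil[id_to_pos[u], id_to_pos[v]] = 0
        log_rows.append(("remove", u, v))

    P = _addition_probability(graph, table, D, pos)
    np.fill_diagonal(P, 0.0)
    # pairs connected after removal are ineligible; just-vacated pairs are not
    cur = lil.tocsr()
    cur.eliminate_zeros()
    P[cur.toarray() > 0] = 0.0
    flat = P.ravel()
    n = graph.n_nodes
    ids = graph.node_ids
    added = []
    for _ in range(m):
        total = flat.sum()
        if total <= 0:
            raise ValueError("addition probability mass exhausted")
        k = rng.choice(n * n, p=flat / total)
        ui, vi = divmod(int(k), n)
        added.append((ui, vi))
        flat[k] = 0.0
    lil = cur.tolil()
    for (ui, vi) in added:
        lil[ui, vi] = 1
        log_rows.append(("add", int(ids[ui]), int(ids[vi])))
    new = graph.with_adjacency(lil.tocsr())
    assert new.n_edges == graph.n_edges, "edge count must be conserved"
    return new, pd.DataFrame(log_rows, columns=["action", "pre_id", "post_id"])


def rewiring_schedule(
    graph: Connectome, config: RewiringConfig
) -> tuple[Connectome, pd.DataFrame, pd.DataFrame]:
    """Apply the configured (D, m) steps in order.

    Returns the final connectome, the concatenated change log, and per-step
    metrics (simplex counts and the fraction of edges rewired so far).
    """
    rng = np.random.default_rng(config.seed)
    current = graph
    logs = []
    metrics = []
    total_rewired = 0
    for step, (D, m) in enumerate(config.schedule):
        table = enumerate_simplices(current, max_dim=config.max_dim)
        current, log = rewiring_step(
            current, D, m, pos=config.pos, seed=rng, table=table,
            max_dim=config.max_dim,
        )
        log.insert(0, "step", step)
        logs.append(log)
        total_rewired += m
        counts = count_simplices(current, max_dim=config.max_dim)
        metrics.append({
            "step": step, "D": D, "m": m,
            "fraction_rewired": total_rewired / max(graph.n_edges, 1),
            **{f"S{d}": c for d, c in counts.items()},
        })
    return current, pd.concat(logs, ignore_index=True), pd.DataFrame(metrics)
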