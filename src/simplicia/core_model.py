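"""Core data structures: neuron/synapse tables, the weighted directed connectome,
subvolume selection, and generic pairwise connectivity statistics.

The canonical in-memory containers are plain :class:`pandas.DataFrame` tables with
standardized column names plus a :class:`Connectome` that pairs a node table with a
CSR adjacency matrix of integer synapse counts.

Canonical neuron-table columns
------------------------------
``neuron_id``  integer identifier, unique after deduplication
``x, y, z``    soma position in micrometres
``synapse_class``  ``"E"`` or ``"I"``
optional: ``cell_type``, ``proofreading_axon``, ``proofreading_dendrite``

Canonical synapse-table columns: ``pre_id``, ``post_id``, ``synapse_count``
(>= 1; one row per connection or per synapse), optional ``size``.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import h5py
import numpy as np
import pandas as pd
import scipy.sparse as sp

logger = logging.getLogger(__name__)

NEURON_COLUMNS = ("neuron_id", "x", "y", "z", "synapse_class")
OPTIONAL_NEURON_COLUMNS = ("cell_type", "proofreading_axon", "proofreading_dendrite")

#: default mapping from source-file column names (EM-release conventions) to
#: canonical names; overridable through a JSON/YAML config dict.
DEFAULT_NEURON_COLUMN_MAP = {
    "pt_root_id": "neuron_id",
    "pt_position_x": "x",
    "pt_position_y": "y",
    "pt_position_z": "z",
    "cell_type": "cell_type",
    "classification_system": "synapse_class",
}
DEFAULT_SYNAPSE_COLUMN_MAP = {
    "pre_pt_root_id": "pre_id",
    "post_pt_root_id": "post_id",
    "size": "size",
}

#: voxel pitch (nm) of the source EM volume, used when positions are voxel indices
VOXEL_RESOLUTION_NM = (4.0, 4.0, 40.0)

CONTAINER_FORMAT_VERSION = 1


class ConnectomeFormatError(RuntimeError):
    """Raised when a serialized connectome container cannot be interpreted."""


# ---------------------------------------------------------------------------
# neuron / synapse tables
# ---------------------------------------------------------------------------

def validate_neuron_table(neurons: pd.DataFrame) -> pd.DataFrame:
    """Validate and normalize a neuron table.

    Ensures canonical columns are present, coordinates are finite, the synapse
    class is always one of {E, I}, and ``neuron_id`` values are unique.
    Returns the table indexed by ``neuron_id`` (original column retained).
    """
    if neurons is None or len(neurons) == 0:
        raise ValueError("neuron table is empty")
    missing = [c for c in NEURON_COLUMNS if c not in neurons.columns]
    if missing:
        raise ValueError(f"neuron table missing columns: {missing}")
    coords = neurons[["x", "y", "z"]].to_numpy(dtype=float)
    bad = ~np.isfinite(coords).all(axis=1)
    if bad.any():
        row = int(np.flatnonzero(bad)[0])
        raise ValueError(
            f"non-finite coordinates in neuron table row {row} "
            f"(neuron_id={neurons['neuron_id'].iloc[row]})"
        )
    cls = neurons["synapse_class"].astype(str)
    bad_cls = ~cls.isin(["E", "I"])
    if bad_cls.any():
        raise ValueError(
            f"synapse_class must be 'E' or 'I'; offending values: "
            f"{sorted(cls[bad_cls].unique())}"
        )
    if neurons["neuron_id"].duplicated().any():
        raise ValueError(
            "duplicate neuron_id values present; call drop_duplicate_neurons first"
        )
    out = neurons.copy()
    out["neuron_id"] = out["neuron_id"].astype(np.int64)
    out["synapse_class"] = cls.values
    return out.set_index(out["neuron_id"].rename(None))


def drop_duplicate_neurons(neurons: pd.DataFrame) -> tuple[pd.DataFrame, int]:
    """Remove ALL rows that share a duplicated ``neuron_id``.

    Duplicated identifiers typically indicate distinct cells merged during
    segmentation; every row of such an id is dropped (not just the extras).
    Returns ``(filtered_table, n_rows_dropped)``.
    """
    dup = neurons["neuron_id"].duplicated(keep=False)
    n_dropped = int(dup.sum())
    if n_dropped:
        logger.info("dropping %d rows with duplicated neuron_id", n_dropped)
    return neurons.loc[~dup].copy(), n_dropped


def _apply_column_map(df: pd.DataFrame, column_map: Mapping[str, str]) -> pd.DataFrame:
    renames = {src: dst for src, dst in column_map.items() if src in df.columns}
    return df.rename(columns=renames)


def read_neuron_table(
    path: str | Path,
    column_map: Mapping[str, str] | None = None,
    positions_in_voxels: bool = False,
) -> pd.DataFrame:
    """Read a neuron table from CSV or Parquet.

    ``column_map`` maps file column names to canonical ones; defaults follow the
    public EM-release conventions (``pt_root_id`` etc.). If ``positions_in_voxels``
    the coordinates are converted to micrometres using the 4 x 4 x 40 nm voxel pitch.
    """
    path = Path(path)
    df = pd.read_parquet(path) if path.suffix == ".parquet" else pd.read_csv(path)
    df = _apply_column_map(df, column_map or DEFAULT_NEURON_COLUMN_MAP)
    if positions_in_voxels:
        for axis, pitch_nm in zip("xyz", VOXEL_RESOLUTION_NM):
            df[axis] = df[axis].astype(float) * pitch_nm / 1000.0
    df, _ = drop_duplicate_neurons(df)
    return validate_neuron_table(df).reset_index(drop=True)


def read_synapse_table(
    path: str | Path, column_map: Mapping[str, str] | None = None
) -> pd.DataFrame:
    """Read a synapse table (CSV or Parquet); rows without an explicit
    ``synapse_count`` column count as one synapse each."""
    path = Path(path)
    df = pd.read_parquet(path) if path.suffix == ".parquet" else pd.read_csv(path)
    df = _apply_column_map(df, column_map or DEFAULT_SYNAPSE_COLUMN_MAP)
    if "synapse_count" not in df.columns:
        df["synapse_count"] = 1
    if (df["synapse_count"] < 1).any():
        raise ValueError("synapse_count values must be positive integers")
    return df


# ---------------------------------------------------------------------------
# Connectome
# ---------------------------------------------------------------------------

class Connectome:
    """A directed simple graph of neurons with integer synapse-count weights.

    Nodes carry the neuron-table attributes; ``adjacency`` is a CSR matrix whose
    row/column order matches ``nodes`` (positional indexing). No self-loops, at
    most one edge per ordered pair, weights >= 1. Reciprocal connections are two
    independent directed edges.
    """

    def __init__(self, nodes: pd.DataFrame, adjacency: sp.spmatrix,
                 meta: dict | None = None):
        adjacency = sp.csr_matrix(adjacency)
        adjacency.sort_indices()
        if adjacency.shape != (len(nodes), len(nodes)):
            raise ValueError("adjacency shape does not match node table")
        if adjacency.nnz and adjacency.diagonal().any():
            raise ValueError("self-loops are not allowed in a Connectome")
        if adjacency.nnz and adjacency.data.min() < 1:
            raise ValueError("edge weights must be >= 1")
        self.nodes = nodes
        self.adjacency = adjacency.astype(np.int64)
        self.meta = dict(meta or {})
        self._id_index = pd.Index(nodes["neuron_id"].to_numpy())

    # -- basic properties ---------------------------------------------------
    @property
    def n_nodes(self) -> int:
        return len(self.nodes)

    @property
    def n_edges(self) -> int:
        return int(self.adjacency.nnz)

    @property
    def node_ids(self) -> np.ndarray:
        return self._id_index.to_numpy()

    @property
    def positions(self) -> np.ndarray:
        return self.nodes[["x", "y", "z"]].to_numpy(dtype=float)

    def ids_to_pos(self, ids: Iterable[int]) -> np.ndarray:
        pos = self._id_index.get_indexer(np.asarray(list(ids), dtype=np.int64))
        if (pos < 0).any():
            raise KeyError("some ids not present in connectome")
        return pos

    def edges(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Return (pre_ids, post_ids, weights) arrays in CSR order."""
        coo = self.adjacency.tocoo()
        ids = self.node_ids
        return ids[coo.row], ids[coo.col], coo.data.copy()

    def has_edge(self, pre_id: int, post_id: int) -> bool:
        i, j = self.ids_to_pos([pre_id, post_id])
        return bool(self.adjacency[i, j])

    def class_mask(self, synapse_class: str) -> np.ndarray:
        return (self.nodes["synapse_class"] == synapse_class).to_numpy()

    # -- derived graphs -----------------------------------------------------
    def subgraph(self, ids: Iterable[int]) -> "Connectome":
        """Induced subgraph on the given neuron ids (order preserved as given)."""
        pos = self.ids_to_pos(ids)
        sub_nodes = self.nodes.iloc[pos].copy()
        sub_adj = self.adjacency[pos][:, pos]
        return Connectome(sub_nodes, sub_adj, meta=self.meta)

    def excitatory_subgraph(self) -> "Connectome":
        return self.subgraph(self.node_ids[self.class_mask("E")])

    def with_adjacency(self, adjacency: sp.spmatrix) -> "Connectome":
        return Connectome(self.nodes, adjacency, meta=self.meta)

    def out_neighbor_lists(self) -> list[np.ndarray]:
        """Sorted positional out-neighbor array per node."""
        a = self.adjacency
        return [a.indices[a.indptr[i]:a.indptr[i + 1]] for i in range(self.n_nodes)]

    def to_networkx(self):
        import networkx as nx

        g = nx.DiGraph()
        for nid, row in self.nodes.iterrows():
            g.add_node(int(row["neuron_id"]))
        pre, post, w = self.edges()
        g.add_weighted_edges_from(zip(pre.tolist(), post.tolist(), w.tolist()))
        return g

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        ne = int(self.class_mask("E").sum())
        return (f"Connectome({self.n_nodes} nodes [{ne} E / "
                f"{self.n_nodes - ne} I], {self.n_edges} edges)")


def build_connectome(neurons: pd.DataFrame, synapses: pd.DataFrame) -> Connectome:
    """Assemble a :class:`Connectome` from neuron and synapse tables.

    Synapse rows whose pre- or postsynaptic id is absent from the neuron table
    are discarded, as are self-loop rows; multiple synapses between an ordered
    pair aggregate into a single weighted edge. Drop counts are logged and
    recorded in ``meta``.
    """
    neurons = validate_neuron_table(
        neurons.reset_index(drop=True) if neurons.index.name else neurons
    ).reset_index(drop=True)
    ids = pd.Index(neurons["neuron_id"])
    n = len(ids)

    if len(synapses) == 0:
        adj = sp.csr_matrix((n, n), dtype=np.int64)
        return Connectome(neurons, adj, meta={"dropped_missing": 0, "dropped_self": 0})

    pre = ids.get_indexer(synapses["pre_id"].to_numpy())
    post = ids.get_indexer(synapses["post_id"].to_numpy())
    counts = synapses.get("synapse_count", pd.Series(1, index=synapses.index))
    counts = counts.to_numpy(dtype=np.int64)
    present = (pre >= 0) & (post >= 0)
    self_loop = present & (pre == post)
    keep = present & ~self_loop
    n_missing = int((~present).sum())
    n_self = int(self_loop.sum())
    if n_missing:
        logger.info("dropped %d synapse rows with unknown endpoints", n_missing)
    if n_self:
        logger.info("dropped %d self-loop synapse rows", n_self)

    adj = sp.coo_matrix(
        (counts[keep], (pre[keep], post[keep])), shape=(n, n), dtype=np.int64
    ).tocsr()
    adj.sum_duplicates()
    return Connectome(
        neurons, adj, meta={"dropped_missing": n_missing, "dropped_self": n_self}
    )


# ---------------------------------------------------------------------------
# subvolume selection
# ---------------------------------------------------------------------------

@dataclass
class SubvolumeGrid:
    """A grid of overlapping rectangles in the horizontal plane.

    Rectangles are ``width x depth`` micrometres on the two horizontal axes,
    arranged in a ``grid_shape`` = (columns, rows) layout and shifted by
    ``shift`` micrometres between neighbors; with shift < width the rectangles
    overlap. ``origin`` anchors the lower corner of the first rectangle; when
    None the grid is centred on the excitatory soma cloud. The vertical axis is
    unbounded.
    """

    width: float = 500.0
    depth: float = 300.0
    grid_shape: tuple[int, int] = (5, 3)
    shift: float = 50.0
    origin: tuple[float, float] | None = None
    horizontal_axes: tuple[str, str] = ("x", "z")
    inhibitory_margin: float = 0.0

    def rectangles(self, neurons: pd.DataFrame | None = None
                   ) -> list[tuple[float, float, float, float]]:
        """Return (u0, v0, u1, v1) bounds per rectangle, row-major."""
        ncol, nrow = self.grid_shape
        if self.origin is not None:
            u_org, v_org = self.origin
        else:
            if neurons is None:
                raise ValueError("origin unset: need a neuron table to centre on")
            emask = neurons["synapse_class"] == "E"
            pts = neurons.loc[emask, list(self.horizontal_axes)].to_numpy(float)
            span_u = self.width + (ncol - 1) * self.shift
            span_v = self.depth + (nrow - 1) * self.shift
            cu, cv = pts.mean(axis=0)
            u_org, v_org = cu - span_u / 2.0, cv - span_v / 2.0
        rects = []
        for r in range(nrow):
            for c in range(ncol):
                u0 = u_org + c * self.shift
                v0 = v_org + r * self.shift
                rects.append((u0, v0, u0 + self.width, v0 + self.depth))
        return rects


def select_subnetworks(
    neurons: pd.DataFrame, grid: SubvolumeGrid
) -> list[tuple[np.ndarray, np.ndarray]]:
    """Select per-rectangle (excitatory-id-set, inhibitory-id-set) pairs.

    Excitatory neurons are admitted iff their soma lies inside the rectangle,
    with half-open bounds [min, max) on each horizontal axis so a grid with
    shift = width tiles the volume without double counting. Inhibitory neurons
    are admitted regardless of position (optionally restricted to an enlarged
    rectangle via ``grid.inhibitory_margin``, following the convention used for
    volumes where the inhibitory population must be bounded too).
    """
    ax_u, ax_v = grid.horizontal_axes
    u = neurons[ax_u].to_numpy(float)
    v = neurons[ax_v].to_numpy(float)
    ids = neurons["neuron_id"].to_numpy(np.int64)
    emask = (neurons["synapse_class"] == "E").to_numpy()
    imask = ~emask

    span_u = u.max() - u.min()
    span_v = v.max() - v.min()
    if grid.width > span_u or grid.depth > span_v:
        warnings.warn(
            "subvolume rectangle larger than the data volume extent", stacklevel=2
        )

    out = []
    for (u0, v0, u1, v1) in grid.rectangles(neurons):
        inside = (u >= u0) & (u < u1) & (v >= v0) & (v < v1)
        e_ids = ids[emask & inside]
        if grid.inhibitory_margin > 0:
            m = grid.inhibitory_margin
            i_inside = (u >= u0 - m) & (u < u1 + m) & (v >= v0 - m) & (v < v1 + m)
            i_ids = ids[imask & i_inside]
        else:
            i_ids = ids[imask]
        out.append((e_ids, i_ids))
    return out


# ---------------------------------------------------------------------------
# pairwise statistics
# ---------------------------------------------------------------------------

def pairwise_connection_stats(
    conn: Connectome,
    group_a: Sequence[int],
    group_b: Sequence[int],
    max_distance: float,
) -> dict[str, float]:
    """Connection probabilities over cross pairs within ``max_distance`` (um).

    Over all ordered pairs (i in A, j in B, i != j) whose soma distance is at
    most ``max_distance``: ``p_ab`` = probability of an i->j edge, ``p_ba`` of a
    j->i edge, ``p_bidirectional`` of both. ``overexpression`` =
    p_bidirectional / (p_ab * p_ba); NaN when a denominator is zero.
    """
    pa = conn.ids_to_pos(group_a)
    pb = conn.ids_to_pos(group_b)
    xyz = conn.positions
    diff = xyz[pa][:, None, :] - xyz[pb][None, :, :]
    dist = np.sqrt((diff ** 2).sum(axis=-1))
    eligible = (dist <= max_distance) & (pa[:, None] != pb[None, :])
    n_pairs = int(eligible.sum())
    if n_pairs == 0:
        warnings.warn("no eligible pairs within max_distance", stacklevel=2)
        nan = float("nan")
        return {"p_ab": nan, "p_ba": nan, "p_bidirectional": nan,
                "overexpression": nan, "n_pairs": 0}
    a_ab = (sp.csr_matrix(conn.adjacency[pa][:, pb]) > 0).toarray()
    a_ba = (sp.csr_matrix(conn.adjacency[pb][:, pa]) > 0).toarray().T
    p_ab = float(a_ab[eligible].mean())
    p_ba = float(a_ba[eligible].mean())
    p_bi = float((a_ab & a_ba)[eligible].mean())
    over = p_bi / (p_ab * p_ba) if p_ab > 0 and p_ba > 0 else float("nan")
    return {"p_ab": p_ab, "p_ba": p_ba, "p_bidirectional": p_bi,
            "overexpression": over, "n_pairs": n_pairs}


# ---------------------------------------------------------------------------
# HDF5 container
# ---------------------------------------------------------------------------

_STRING_DT = h5py.string_dtype(encoding="utf-8")


def save_connectome(conn: Connectome, path: str | Path) -> None:
    """Serialize to a single HDF5 file: node table + CSR edge arrays + metadata.

    The writer is deterministic (fixed dtypes, no timestamps) so that
    save(load(save(x))) is byte-identical.
    """
    path = Path(path)
    with h5py.File(path, "w", libver="earliest", track_order=False) as f:
        f.attrs["format"] = "simplicia-connectome"
        f.attrs["format_version"] = CONTAINER_FORMAT_VERSION
        f.attrs["units"] = "um"
        f.attrs["meta"] = json.dumps(conn.meta, sort_keys=True)
        grp = f.create_group("nodes")
        for col in conn.nodes.columns:
            vals = conn.nodes[col].to_numpy()
            if vals.dtype == object or vals.dtype.kind in "US":
                ds = grp.create_dataset(
                    col, data=np.asarray(vals, dtype=object), dtype=_STRING_DT,
                    track_times=False)
            else:
                ds = grp.create_dataset(col, data=vals, track_times=False)
            del ds
        grp.attrs["column_order"] = json.dumps(list(conn.nodes.columns))
        e = f.create_group("edges")
        a = conn.adjacency
        e.create_dataset("indptr", data=a.indptr.astype(np.int64), track_times=False)
        e.create_dataset("indices", data=a.indices.astype(np.int64), track_times=False)
        e.create_dataset("weights", data=a.data.astype(np.int64), track_times=False)


def load_connectome(path: str | Path) -> Connectome:
    """Load a connectome written by :func:`save_connectome`."""
    with h5py.File(Path(path), "r") as f:
        if f.attrs.get("format") != "simplicia-connectome":
            raise ConnectomeFormatError(f"{path}: not a simplicia connectome file")
        version = int(f.attrs.get("format_version", -1))
        if version != CONTAINER_FORMAT_VERSION:
            raise ConnectomeFormatError(
                f"{path}: unsupported container version {version} "
                f"(expected {CONTAINER_FORMAT_VERSION})"
            )
        cols = json.loads(f["nodes"].attrs["column_order"])
        data = {}
        for col in cols:
            vals = f["nodes"][col][()]
            if vals.dtype.kind in "OS":
                vals = np.asarray([v.decode() if isinstance(v, bytes) else v
                                   for v in vals], dtype=object)
            data[col] = vals
        nodes = pd.DataFrame(data, columns=cols)
        n = len(nodes)
        adj = sp.csr_matrix(
            (f["edges"]["weights"][()], f["edges"]["indices"][()],
             f["edges"]["indptr"][()]),
            shape=(n, n),
        )
        meta = json.loads(f.attrs.get("meta", "{}"))
    return Connectome(nodes, adj, meta=meta)
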