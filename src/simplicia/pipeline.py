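"""Orchestration: the structure-activity correlation analysis, target-dimension
selection, and an end-to-end analysis runner for synthetic connectomes.

The runner executes the full chain — generate (or load) a connectome,
enumerate simplices, measure divergence, position the inhibition, build the
disynaptic-inhibition matrix with its shuffle controls, run the targeting and
disinhibition tests, group the simplices, score neighborhood complexity, and
optionally rewire and correlate activity — and emits all tables plus a JSON
manifest with seeds and per-stage hashes so a rerun with the same root seed is
verifiably identical.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import inhibition_topology as it
from . import neighborhoods as nb
from . import null_models as nm
from . import simplex_groups as sg
from . import synthetic_data as sd
from .core_model import Connectome
from .simplices import SimplexTable, enumerate_simplices, unique_fraction_by_position, edge_max_dimension

__all__ = ["AnalysisConfig", "correlation_by_edge_dimension",
           "select_target_dimension", "run_analysis"]


# ---------------------------------------------------------------------------
# structure-activity correlation
# ---------------------------------------------------------------------------

def correlation_by_edge_dimension(
    corr_matrices: list[pd.DataFrame] | pd.DataFrame,
    edge_dims: dict[tuple[int, int], int],
    last_edges: dict[int, np.ndarray] | None = None,
    z_score: bool = True,
) -> pd.DataFrame:
    """Mean (z-scored) activity correlation per maximal edge simplex dimension.

    ``corr_matrices`` is one pairwise-Pearson matrix per session (node ids on
    both axes); single-session input may be passed directly. Correlations are
    z-scored within each session over all valid off-diagonal pairs, then
    connected pairs are grouped by the maximal dimension of simplices their
    edge participates in and averaged across sessions. ``last_edges`` maps
    dimension n to an (m, 2) array of last connections (position n-1 -> n,
    with repetition) for the last-edge variant. Baselines for connected and
    unconnected pairs are included as rows with group "connected" /
    "unconnected".

    Returns a tidy frame: variant, group, mean, sem, n_pairs.
    """
    if isinstance(corr_matrices, pd.DataFrame):
        corr_matrices = [corr_matrices]
    per_session: dict[tuple[str, object], list[np.ndarray]] = {}

    for C in corr_matrices:
        ids = np.asarray(C.index)
        if len(ids) < 2:
            import warnings

            warnings.warn("session with < 2 nodes skipped", stacklevel=2)
            continue
        vals = C.to_numpy(dtype=float)
        off = ~np.eye(len(ids), dtype=bool)
        valid = off & np.isfinite(vals)
        if z_score:
            mu, sdv = vals[valid].mean(), vals[valid].std()
            if sdv <= 1e-12 * max(1.0, abs(mu)):  # degenerate spread
                sdv = np.inf
            z = (vals - mu) / sdv if np.isfinite(sdv) else np.zeros_like(vals)
        else:
            z = vals
        idx = {int(v): k for k, v in enumerate(ids)}
        conn_mask = np.zeros_like(valid)
        by_dim: dict[int, list[float]] = {}
        for (u, v), dim in edge_dims.items():
            if int(u) in idx and int(v) in idx:
                i, j = idx[int(u)], idx[int(v)]
                if valid[i, j]:
                    conn_mask[i, j] = True
                    by_dim.setdefault(dim, []).append(z[i, j])
        for dim, samples in by_dim.items():
            per_session.setdefault(("all_edges", dim), []).append(
                np.asarray(samples))
        if last_edges:
            for dim, pairs in last_edges.items():
                samples = [z[idx[int(u)], idx[int(v)]]
                           for u, v in np.asarray(pairs).reshape(-1, 2)
                           if int(u) in idx and int(v) in idx
                           and valid[idx[int(u)], idx[int(v)]]]
                if samples:
                    per_session.setdefault(("last_edge", dim), []).append(
                        np.asarray(samples))
        per_session.setdefault(("baseline", "connected"), []).append(
            z[valid & conn_mask])
        per_session.setdefault(("baseline", "unconnected"), []).append(
            z[valid & ~conn_mask])

    rows = []
    for (variant, group), chunks in sorted(per_session.items(),
                                           key=lambda kv: (kv[0][0], str(kv[0][1]))):
        session_means = [c.mean() for c in chunks if len(c)]
        if not session_means:
            continue
        pooled = np.concatenate([c for c in chunks if len(c)])
        sem = (np.std(session_means, ddof=1) / np.sqrt(len(session_means))
               if len(session_means) > 1
               else pooled.std(ddof=1) / np.sqrt(len(pooled)) if len(pooled) > 1
               else np.nan)
        rows.append((variant, group, float(np.mean(session_means)), float(sem),
                     int(len(pooled))))
    return pd.DataFrame(rows, columns=["variant", "group", "mean", "sem", "n_pairs"])


def select_target_dimension(table: SimplexTable, min_dim: int = 1) -> int:
    """The dimension where divergence is strongest: argmax over dimensions of
    the source-normalized unique-neuron fraction at the target position, ties
    broken toward the lower dimension."""
    best_dim, best_val = min_dim, -np.inf
    for dim in sorted(d for d in table.by_dim if d >= min_dim):
        if table.n_simplices(dim) == 0:
            continue
        _, normalized = unique_fraction_by_position(table, dim)
        val = normalized[-1]
        if np.isfinite(val) and val > best_val:
            best_dim, best_val = dim, val
    return best_dim


# ---------------------------------------------------------------------------
# end-to-end runner
# ---------------------------------------------------------------------------

@dataclass
class AnalysisConfig:
    """Fully-serializable settings for a synthetic end-to-end run.

    Every random operation is seeded from ``seed`` through a SeedSequence
    spawn, so identical configs yield identical outputs.
    """

    seed: int = 0
    n_e: int = 400
    n_i: int = 80
    volume: tuple[float, float, float] = (400.0, 400.0, 400.0)
    distance_a: float = 0.03
    distance_b: float = 150.0
    plant: dict = field(default_factory=dict)   # PlantSpec overrides
    n_shuffles: int = 20
    targeting_threshold: float = 1e-6
    percentile: float = 95.0
    resolution: float = 2.2
    max_dim: int | None = None
    run_rewiring: bool = False
    rewiring_schedule: list[tuple[int, int]] = field(default_factory=lambda: [(2, 20)])
    run_activity: bool = False
    activity_T: int = 2000
    corr_profile: dict[int, float] = field(
        default_factory=lambda: {1: 0.05, 3: 0.15, 5: 0.3})
    n_complexity_nodes: int = 50
    output_dir: str | None = None


def _hash_obj(obj) -> str:
    def default(o):
        if isinstance(o, np.ndarray):
            return o.tolist()
        if isinstance(o, (np.integer, np.floating)):
            return o.item()
        return str(o)

    return hashlib.sha256(
        json.dumps(obj, sort_keys=True, default=default).encode()
    ).hexdigest()[:16]


def run_analysis(config: AnalysisConfig) -> dict:
    """Execute the full synthetic analysis chain; returns a result bundle.

    The bundle maps stage names to tables/arrays and carries a ``manifest``
    with the config, per-stage content hashes and the seeds used. Stage
    failures propagate as exceptions naming the stage.
    """
    seeds = np.random.SeedSequence(config.seed).spawn(12)
    results: dict = {}
    manifest: dict = {"config": asdict(config), "stages": {}}

    def stage(name, fn):
        try:
            out = fn()
        except Exception as err:
            raise RuntimeError(f"pipeline stage {name!r} failed: {err}") from err
        results[name] = out
        return out

    # --- generate ---------------------------------------------------------
    neurons = stage("neurons", lambda: sd.make_neurons(
        config.n_e, config.n_i, config.volume,
        seed=np.random.default_rng(seeds[0])))
    params = sd.DistanceModelParams.uniform(config.distance_a, config.distance_b)
    base = stage("base_connectome", lambda: sd.sample_distance_connectome(
        neurons, params, seed=np.random.default_rng(seeds[1])))
    spec = sd.PlantSpec(**config.plant)
    planted, _plant_log = stage("planted", lambda: sd.plant_divergent_simplices(
        base, spec, seed=np.random.default_rng(seeds[2])))
    e_table = enumerate_simplices(planted.excitatory_subgraph(),
                                  max_dim=config.max_dim)
    conn, dis_ids = stage("inhibition_wiring", lambda: sd.wire_biased_inhibition(
        planted, e_table, spec, seed=np.random.default_rng(seeds[3])))
    results["disinhibitory_ids"] = dis_ids

    # --- simplices and divergence ----------------------------------------
    exc = conn.excitatory_subgraph()
    table = stage("simplices", lambda: enumerate_simplices(
        exc, max_dim=config.max_dim))
    target_dim = stage("target_dimension", lambda: select_target_dimension(
        table, min_dim=2))
    frac, norm = unique_fraction_by_position(table, target_dim)
    results["unique_fraction"] = frac
    results["unique_fraction_normalized"] = norm

    # --- inhibition profiles and disynaptic matrix ------------------------
    profile = stage("degree_by_position", lambda: it.inhibitory_degree_by_position(
        conn, table, target_dim))
    tensors = stage("tensors", lambda: it.inhibition_tensors(
        table, target_dim, conn))
    I = stage("disynaptic", lambda: it.disynaptic_inhibition(tensors))
    results["symmetry"] = it.symmetry_score(I) if I.shape[0] >= 2 else np.nan
    rng_sh = np.random.default_rng(seeds[4])
    shuffled = []
    shuffled_scores = []
    for _ in range(config.n_shuffles):
        s_ei, s_ie = nm.shuffle_inhibition_columns(
            tensors.m_ei_reduced, tensors.m_ie_reduced, seed=rng_sh)
        Ish = np.asarray((s_ei @ s_ie.T).todense(), dtype=np.int64)
        shuffled.append(Ish)
        if Ish.shape[0] >= 2:
            shuffled_scores.append(it.symmetry_score(Ish))
    results["symmetry_shuffled"] = (float(np.nanmean(shuffled_scores))
                                    if shuffled_scores else np.nan)

    # disjoint source/target sides (0..2 and dim-2..dim at dim >= 5, narrowed
    # symmetrically at lower dimensions)
    src_hi = min(2, (target_dim - 1) // 2)
    tgt_lo = max(src_hi + 1, target_dim - 2)
    o_src = it.overlap_matrix(table, target_dim, 0, src_hi)
    o_tgt = it.overlap_matrix(table, target_dim, tgt_lo, target_dim)
    o_any = it.overlap_matrix(table, target_dim, 0, target_dim)
    results["overlap_correlations"] = it.overlap_inhibition_correlation(
        o_src, o_tgt, I)

    # --- targeting / disinhibition ----------------------------------------
    targeting = stage("targeting", lambda: it.inhibitory_targeting_test(
        conn, threshold=config.targeting_threshold))
    sdeg = it.simplex_degrees_of_inhibitory(
        conn, table, target_dim,
        source_positions=tuple(range(src_hi + 1)),
        target_positions=tuple(range(tgt_lo, target_dim + 1)))
    results["simplex_degrees"] = sdeg
    results["disinhibition_profile"] = it.disinhibition_profile(
        conn, targeting, sdeg)

    # --- groups ------------------------------------------------------------
    src_groups = stage("source_groups", lambda: sg.cluster_simplices(
        o_src, resolution=config.resolution, seed=int(seeds[5].generate_state(1)[0] % 2**31),
        flavor="source"))
    tgt_groups = sg.cluster_simplices(
        o_tgt, resolution=config.resolution,
        seed=int(seeds[6].generate_state(1)[0] % 2**31), flavor="target")
    results["target_groups"] = tgt_groups
    results["group_network"] = sg.group_network(
        src_groups, tgt_groups, o_any, I, shuffled,
        percentile=config.percentile)
    results["group_sizes"] = {
        "source": sg.group_sizes(src_groups),
        "target": sg.group_sizes(tgt_groups),
    }

    # --- neighborhood complexity ------------------------------------------
    control = nm.configuration_model(exc, seed=np.random.default_rng(seeds[7]))
    core_nodes = np.unique(table.simplices(target_dim)) if \
        table.n_simplices(target_dim) else exc.node_ids
    rng_nodes = np.random.default_rng(seeds[8])
    pick = rng_nodes.choice(core_nodes,
                            size=min(config.n_complexity_nodes, len(core_nodes)),
                            replace=False)
    records = [nb.neighborhood_complexity(exc, control, int(v)) for v in pick]
    results["complexity_by_position"] = nb.complexity_by_position(records, table)

    # --- optional rewiring --------------------------------------------------
    if config.run_rewiring:
        from .rewiring import RewiringConfig, rewiring_schedule

        rw_cfg = RewiringConfig(
            schedule=config.rewiring_schedule,
            seed=int(seeds[9].generate_state(1)[0] % 2**31),
            max_dim=config.max_dim)
        _, _, rw_metrics = rewiring_schedule(exc, rw_cfg)
        results["rewiring_metrics"] = rw_metrics

    # --- optional activity --------------------------------------------------
    if config.run_activity:
        dmap = edge_max_dimension(table, exc)
        traces = sd.synth_activity(
            exc.node_ids, dmap, config.corr_profile, T=config.activity_T,
            seed=np.random.default_rng(seeds[10]))
        C = traces.corr()
        results["activity_correlation"] = correlation_by_edge_dimension(C, dmap)

    # --- manifest -----------------------------------------------------------
    for name in ("target_dimension", "symmetry", "unique_fraction_normalized"):
        manifest["stages"][name] = _hash_obj(results.get(name))
    manifest["stages"]["simplex_counts"] = _hash_obj(table.counts())
    manifest["stages"]["degree_profile"] = _hash_obj(
        profile.to_dict(orient="list"))
    results["manifest"] = manifest

    if config.output_dir:
        _write_bundle(results, Path(config.output_dir))
    return results


def _write_bundle(results: dict, outdir: Path) -> None:
    outdir.mkdir(parents=True, exist_ok=True)
    for name, obj in results.items():
        if isinstance(obj, pd.DataFrame):
            obj.to_csv(outdir / f"{name}.csv", index=False)
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(results["manifest"], fh, indent=2, default=str)
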