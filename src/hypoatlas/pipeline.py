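"""End-to-end demo pipeline on synthetic data.

``run_all`` exercises every stage in sequence — synthetic generation, QC,
ensemble consensus clustering, tree building and pruning, cross-species
matching, spatial region assignment and effector-gene selection — writing all
outputs (and a JSON-lines run log) into one directory.  Everything is a pure
function of the configuration and seed.
"""

from __future__ import annotations

import json
import platform
from datetime import datetime, timezone
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__, io
from .config import PipelineConfig
from .consensus import consensus_partition, run_leiden_ensemble
from .crossspecies import (
    adjust_correlations,
    build_match_graph,
    correlate_centroids,
    match_summary,
    prune_match_graph,
)
from .effectors import select_effector_genes
from .qc import drop_doublet_clusters, filter_nuclei
from .spatial import assign_clusters, cluster_spots, score_region_assignment
from .synthetic import (
    HierarchySpec,
    SpatialSpec,
    SpeciesPairSpec,
    planted_affinity,
    simulate_counts,
    simulate_gwas_tables,
    simulate_hierarchy,
    simulate_spatial,
    simulate_species_pair,
)
from .tree import build_tree, prune_tree


def run_all(config: PipelineConfig | None = None, outdir=None, seed: int | None = None) -> dict:
    """Run the full synthetic pipeline; returns a summary dict."""
    config = config or PipelineConfig()
    seed = config.seed if seed is None else int(seed)
    outdir = Path(outdir if outdir is not None else config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    sim = config.simulate
    log_path = outdir / "run_log.jsonl"
    log_f = log_path.open("w")

    def log(event: str, **payload) -> None:
        rec = {"event": event, **payload}
        log_f.write(json.dumps(rec, default=str) + "\n")

    log(
        "start",
        config_hash=config.digest(),
        seed=seed,
        version=__version__,
        python=platform.python_version(),
        timestamp=datetime.now(timezone.utc).isoformat(),
    )
    summary: dict = {"seed": seed, "config_hash": config.digest()}

    # --- synthetic hierarchy + counts -------------------------------------
    hspec = HierarchySpec(
        levels=tuple(sim.levels),
        cells_per_leaf=sim.cells_per_leaf,
        embedding_dim=sim.embedding_dim,
        separation=sim.separation,
        noise_sd=sim.noise_sd,
        seed=seed,
    )
    embedding, cells, truth = simulate_hierarchy(hspec)
    counts, _ = simulate_counts(
        truth,
        cells,
        n_genes=sim.n_genes,
        markers_per_leaf=sim.markers_per_leaf,
        seed=seed + 1,
    )

    # --- QC ----------------------------------------------------------------
    leaf_col = f"true_C{len(sim.levels) - 1}"
    kept, _, qc_summary = filter_nuclei(cells, config.qc)
    kept = drop_doublet_clusters(kept, leaf_col, config.qc)
    keep_idx = kept.index.to_numpy()
    embedding_k = embedding[keep_idx]
    counts_k = counts.subset_cells(keep_idx)
    kept = kept.reset_index(drop=True)
    io.write_cell_table(kept, outdir / "cells_kept.tsv")
    summary["qc"] = qc_summary
    summary["n_cells_final"] = int(len(kept))
    log("qc", **qc_summary)

    # --- consensus tree ----------------------------------------------------
    layers = {}
    for i, (res, k) in enumerate(
        zip(config.clustering.resolutions, config.clustering.k_neighbors)
    ):
        ens = run_leiden_ensemble(
            embedding_k,
            resolution=res,
            n_runs=config.clustering.n_runs,
            k_neighbors=int(k),
            base_seed=seed + 100 * (i + 1),
        )
        layers[res] = consensus_partition(ens, seed=seed)
    tree = build_tree(layers, embedding=embedding_k, cell_ids=kept["cell_id"].to_numpy())
    pruned = prune_tree(tree, counts_k, kept, config.prune)
    io.export_tree(pruned, outdir / "tree.json", "json")
    io.export_tree(pruned, outdir / "tree.newick", "newick")
    label_table = pd.DataFrame({"cell_id": kept["cell_id"]})
    for lvl in range(pruned.n_levels):
        label_table[f"C{lvl}"] = pruned.labels_at_level(lvl)
    io.write_labels(label_table, outdir / "labels.tsv")
    summary["tree"] = {
        "levels": pruned.n_levels,
        "clusters_per_level": [len(pruned.nodes_at_level(l)) for l in range(pruned.n_levels)],
        "reconciliation_cost": tree.reconciliation_cost,
        "n_merges": len(pruned.prune_log),
    }
    log("tree", **summary["tree"])

    # --- cross-species matching ---------------------------------------------
    sspec = SpeciesPairSpec(
        shared_leaves=sim.shared_leaves,
        a_only_leaves=sim.private_leaves,
        b_only_leaves=sim.private_leaves,
        seed=seed + 2,
    )
    emb_j, species, labels_j, truth_match = simulate_species_pair(sspec)
    idx = np.arange(len(labels_j))
    labels_a = pd.Series(labels_j[species == "A"], index=idx[species == "A"])
    labels_b = pd.Series(labels_j[species == "B"], index=idx[species == "B"])
    corr = correlate_centroids(emb_j, labels_a, labels_b)
    adjusted = adjust_correlations(corr)
    graph = prune_match_graph(build_match_graph(adjusted, config.match, raw=corr))
    matches = match_summary(graph, clusters_a=corr.index, clusters_b=corr.columns)
    matches.to_csv(outdir / "matches.tsv", sep="\t", index=False)
    planted = set(zip(truth_match["cluster_a"], truth_match["cluster_b"]))
    found = {
        (u[1], v[1]) if u[0] == "A" else (v[1], u[1])
        for u, v in graph.edges
    }
    summary["cross_species"] = {
        "planted_pairs": len(planted),
        "recovered_pairs": len(planted & found),
        "extra_pairs": len(found - planted),
    }
    log("cross_species", **summary["cross_species"])

    # --- spatial regions -----------------------------------------------------
    aff = planted_affinity(sim.n_regions, sim.n_planted_spatial, sim.n_flat_spatial)
    pspec = SpatialSpec(
        n_regions=sim.n_regions,
        spots_per_region=sim.spots_per_region,
        n_clusters=sim.n_planted_spatial + sim.n_flat_spatial,
        affinity=tuple(map(tuple, aff)),
        noise_sd=sim.spatial_noise_sd,
        seed=seed + 3,
    )
    abundance, true_regions, truth_map = simulate_spatial(pspec)
    regions = cluster_spots(abundance, k_neighbors=10, resolution=0.5, seed=seed)
    table = score_region_assignment(abundance, regions)
    assigned = assign_clusters(table)
    table["assigned"] = table["cluster"].map(lambda c: assigned.get(c) or "NA")
    table.to_csv(outdir / "region_assignments.tsv", sep="\t", index=False)
    summary["spatial"] = {
        "n_regions_found": int(regions.nunique()),
        "n_assigned": sum(1 for v in assigned.values() if v is not None),
        "n_na": sum(1 for v in assigned.values() if v is None),
    }
    log("spatial", **summary["spatial"])

    # --- effector genes -------------------------------------------------------
    spec_df, rank_df = simulate_gwas_tables(
        n_genes=sim.n_gwas_genes,
        n_celltypes=sim.n_celltypes,
        planted_effectors=sim.n_planted_effectors,
        seed=seed + 4,
    )
    effectors = select_effector_genes(spec_df, rank_df, config.effectors)
    effectors.to_csv(outdir / "effectors.tsv", sep="\t", index=False)
    summary["effectors"] = {"n_selected": int(len(effectors))}
    log("effectors", **summary["effectors"])

    log("done", summary=summary)
    log_f.close()
    return summary
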