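"""Spatial region definition and cluster -> region assignment.

Spots are clustered on their deconvolution-abundance profiles into regions.
Each transcriptomic cluster is then scored per region: its regional mean
abundance is centred by the median of its regional means ("adjusted
abundance") and divided by the within-region median absolute deviation of its
spot-level abundances — the ``mad_x`` score.  A cluster is assigned to its
top-adjusted-abundance region only when that region's mad_x exceeds a
threshold (default 10, strict); otherwise the assignment is NA.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from ._validate import ValidationError, require
from .consensus import build_knn_graph
from .containers import CountMatrix

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class SignatureGeneFilterConfig:
    """Detection-based gene filter for deconvolution reference signatures."""

    min_cell_fraction: float = 0.08
    rescue_min_fraction: float = 0.0005
    rescue_min_nonzero_mean: float = 1.4

    def __post_init__(self) -> None:
        require(0 < self.min_cell_fraction < 1, "min_cell_fraction must be in (0, 1)")
        require(0 < self.rescue_min_fraction < 1, "rescue_min_fraction must be in (0, 1)")
        require(self.rescue_min_nonzero_mean > 0, "rescue_min_nonzero_mean must be positive")


def filter_signature_genes(
    counts: CountMatrix, cfg: SignatureGeneFilterConfig | None = None
) -> list:
    """Genes detected broadly, or rescued by a high non-zero mean.

    A gene is kept when it is expressed in at least ``min_cell_fraction`` of
    cells, or when it is expressed in at least ``rescue_min_fraction`` of
    cells and the mean of its nonzero counts exceeds
    ``rescue_min_nonzero_mean``.
    """
    cfg = cfg or SignatureGeneFilterConfig()
    frac = counts.detection_fraction()
    total = np.asarray(counts.matrix.sum(axis=0)).ravel()
    n_nonzero = np.asarray((counts.matrix > 0).sum(axis=0)).ravel()
    with np.errstate(divide="ignore", invalid="ignore"):
        nonzero_mean = np.where(n_nonzero > 0, total / np.maximum(n_nonzero, 1), 0.0)
    keep = (frac >= cfg.min_cell_fraction) | (
        (frac >= cfg.rescue_min_fraction) & (nonzero_mean > cfg.rescue_min_nonzero_mean)
    )
    if not keep.any():
        raise ValidationError("no gene passes the signature filter")
    return list(counts.genes[keep])


def cluster_spots(
    abundance: pd.DataFrame,
    k_neighbors: int = 15,
    resolution: float = 1.0,
    seed: int = 0,
    standardize: bool = True,
) -> pd.Series:
    """Leiden regions from spot abundance profiles.

    Abundance columns are z-scored per cluster (optional) before building the
    kNN graph, so high-abundance cell types do not dominate the metric.
    Region ids are ``R0``, ``R1``, ... ordered by first occurrence.
    """
    import leidenalg

    require(len(abundance) >= 2, "need at least 2 spots")
    if k_neighbors >= len(abundance):
        raise ValidationError("k_neighbors must be smaller than the number of spots")
    x = abundance.to_numpy(dtype=float)
    if np.all(x == x[0]):
        # all spots identical: a single region, no graph needed
        return pd.Series(["R0"] * len(abundance), index=abundance.index, name="region")
    if standardize:
        sd = x.std(axis=0)
        x = (x - x.mean(axis=0)) / np.where(sd > 0, sd, 1.0)
    graph = build_knn_graph(x, k_neighbors)
    part = leidenalg.find_partition(
        graph,
        leidenalg.RBConfigurationVertexPartition,
        resolution_parameter=resolution,
        seed=int(seed),
        n_iterations=2,
    )
    membership = np.asarray(part.membership)
    # stable ids in order of first appearance
    remap: dict[int, str] = {}
    labels = []
    for m in membership:
        if m not in remap:
            remap[m] = f"R{len(remap)}"
        labels.append(remap[m])
    return pd.Series(labels, index=abundance.index, name="region")


def merge_regions(labels: pd.Series, merge_map: dict) -> pd.Series:
    """Relabel regions by a curation map; unmapped regions pass through."""
    return labels.map(lambda r: merge_map.get(r, r)).rename("region")


def score_region_assignment(
    abundance: pd.DataFrame, regions: pd.Series
) -> pd.DataFrame:
    """Per (cluster, region) abundance scores: mean, adjusted mean, MAD, mad_x.

    For cluster c and region r, ``mean`` is the average spot abundance of c in
    r, ``adj`` subtracts the median over regions of c's regional means, and
    ``mad`` is the (unscaled) median absolute deviation of c's spot abundances
    within r, floored at 1e-6 times the global mean abundance; ``mad_x`` is
    ``adj / mad``.
    """
    regions = regions.reindex(abundance.index)
    if regions.isna().any():
        raise ValidationError("every spot must have a region label")
    region_ids = sorted(set(regions), key=str)
    small = [r for r in region_ids if (regions == r).sum() < 3]
    if small:
        warnings.warn(f"regions with fewer than 3 spots (MAD unreliable): {small}")

    global_mean = float(abundance.to_numpy().mean())
    eps = max(1e-6 * abs(global_mean), 1e-12)

    rows = []
    means = {}
    for r in region_ids:
        sub = abundance.loc[(regions == r).to_numpy()]
        means[r] = sub.mean(axis=0)
    means_df = pd.DataFrame(means)  # clusters x regions
    medians = means_df.median(axis=1)

    for cluster in abundance.columns:
        for r in region_ids:
            spot_vals = abundance.loc[(regions == r).to_numpy(), cluster].to_numpy()
            mad = float(np.median(np.abs(spot_vals - np.median(spot_vals))))
            mad_floored = max(mad, eps)
            mean = float(means_df.at[cluster, r])
            adj = mean - float(medians[cluster])
            rows.append(
                {
                    "cluster": cluster,
                    "region": r,
                    "mean": mean,
                    "adj": adj,
                    "mad": mad,
                    "mad_x": adj / mad_floored,
                    "mad_floored": mad < eps,
                }
            )
    return pd.DataFrame(rows)


def assign_clusters(
    table: pd.DataFrame, threshold: float = 10.0, overrides: dict | None = None
) -> dict:
    """Cluster -> region (or None) from an assignment table.

    The candidate region is the one with the largest adjusted abundance
    (ties: lexicographically smallest region id); it is assigned only when its
    ``mad_x`` strictly exceeds ``threshold``.  Manual overrides are applied
    last and logged.
    """
    out: dict = {}
    for cluster, sub in table.groupby("cluster"):
        sub = sub.sort_values(["adj", "region"], ascending=[False, True], kind="mergesort")
        best = sub.iloc[0]
        out[cluster] = best["region"] if best["mad_x"] > threshold else None
    for cluster, region in (overrides or {}).items():
        logger.info("manual region override: %s -> %s (was %s)", cluster, region, out.get(cluster))
        out[cluster] = region
    return out


def propagate_assignments(tree, parent_assignments: dict) -> dict:
    """Children inherit their parent's region assignment (or NA)."""
    child_map: dict = {}
    for parent_id, region in parent_assignments.items():
        for child in tree.nodes[parent_id].children:
            child_map[child] = region
    return child_map
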