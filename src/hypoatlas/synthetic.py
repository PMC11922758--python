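"""Synthetic data with planted ground truth for every pipeline stage.

The generators emulate the *shapes* the pipeline consumes, not the biology
that produced them:

* a latent embedding with a planted nested cluster hierarchy (Gaussian blobs
  around recursively placed centroids) standing in for an integrated
  variational embedding;
* Gamma-Poisson counts with planted marker genes and multiplicative
  log-normal batch factors;
* two "species" sharing a subset of clusters whose centroids diverge by a
  controllable amount in a joint embedding;
* spot x cluster deconvolution-abundance maps with planted spatial regions;
* gene specificity and association-rank tables with planted effector genes.

All generators are pure functions of their spec (including the seed).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.sparse as sp

from ._validate import ValidationError, require
from .containers import CountMatrix
from .tree import ClusterTree

# ---------------------------------------------------------------------------
# hierarchy
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class HierarchySpec:
    """Planted cluster hierarchy in a latent embedding.

    ``levels`` lists the branching factor at each level, coarse to fine;
    sibling centroids at the finest level are exactly ``separation`` apart,
    and the spacing triples at each coarser level so that coarse structure
    dominates.  Cells are Gaussian with ``noise_sd`` around their leaf
    centroid.  ``donor_imbalance`` is the probability that a cell takes its
    leaf's "home" donor instead of a uniformly random one.
    """

    levels: tuple = (3, 4)
    cells_per_leaf: int = 200
    embedding_dim: int = 10
    separation: float = 8.0
    noise_sd: float = 1.0
    n_donors: int = 4
    n_batches: int = 2
    donor_imbalance: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        require(len(self.levels) >= 1, "levels must be non-empty")
        require(all(int(b) >= 1 for b in self.levels), "branching factors must be >= 1")
        require(self.cells_per_leaf > 0, "cells_per_leaf must be positive")
        require(self.embedding_dim > 0, "embedding_dim must be positive")
        require(self.embedding_dim >= max(self.levels), "embedding_dim must be >= max branching factor")
        require(self.separation >= 0, "separation must be nonnegative")
        require(self.noise_sd > 0, "noise_sd must be positive")
        require(self.n_donors > 0 and self.n_batches > 0, "donor/batch counts must be positive")
        require(0 <= self.donor_imbalance <= 1, "donor_imbalance must be in [0, 1]")

    @property
    def n_leaves(self) -> int:
        return int(np.prod(self.levels))


def _equidistant_children(
    parent: np.ndarray, n: int, distance: float, rng: np.random.Generator
) -> np.ndarray:
    """n points, pairwise exactly ``distance`` apart, centred on ``parent``."""
    dim = parent.shape[0]
    if n == 1:
        return parent[None, :].copy()
    # centred simplex with unit pairwise distances, randomly oriented
    simplex = np.eye(n) / np.sqrt(2.0)
    simplex -= simplex.mean(axis=0)
    basis, _ = np.linalg.qr(rng.normal(size=(dim, n)))
    return parent + distance * simplex @ basis[:, :n].T


def simulate_hierarchy(spec: HierarchySpec):
    """Embedding, cell table and truth tree for a planted hierarchy.

    Returns ``(embedding, cells, truth)`` where ``embedding`` is a
    cells x dim array, ``cells`` a cell table (ids, donor, batch, sample and
    nominal QC columns) and ``truth`` the planted :class:`ClusterTree`.
    """
    rng = np.random.default_rng(spec.seed)
    depth = len(spec.levels)

    centroids = [np.zeros(spec.embedding_dim)]
    paths = [()]  # label path per current-level node
    for lvl, branching in enumerate(spec.levels):
        # sibling spacing triples at each coarser level so that clusters from
        # different coarse groups never come closer than true siblings
        dist = spec.separation * (3.0 ** (depth - 1 - lvl))
        nxt_centroids, nxt_paths = [], []
        for parent_c, parent_p in zip(centroids, paths):
            kids = _equidistant_children(parent_c, int(branching), dist, rng)
            for j in range(int(branching)):
                nxt_centroids.append(kids[j])
                nxt_paths.append(parent_p + (j,))
        centroids, paths = nxt_centroids, nxt_paths

    n_leaves = len(paths)
    n_cells = n_leaves * spec.cells_per_leaf
    leaf_of_cell = np.repeat(np.arange(n_leaves), spec.cells_per_leaf)
    embedding = np.vstack(
        [
            centroids[leaf]
            + rng.normal(scale=spec.noise_sd, size=(spec.cells_per_leaf, spec.embedding_dim))
            for leaf in range(n_leaves)
        ]
    )

    donors = np.array([f"donor{d}" for d in rng.integers(spec.n_donors, size=n_cells)], dtype=object)
    if spec.donor_imbalance > 0:
        home = rng.integers(spec.n_donors, size=n_leaves)
        take_home = rng.random(n_cells) < spec.donor_imbalance
        donors[take_home] = np.array(
            [f"donor{home[leaf]}" for leaf in leaf_of_cell[take_home]], dtype=object
        )
    batches = np.array([f"batch{b}" for b in rng.integers(spec.n_batches, size=n_cells)], dtype=object)

    cell_ids = np.array([f"cell{i:06d}" for i in range(n_cells)], dtype=object)
    cells = pd.DataFrame(
        {
            "cell_id": cell_ids,
            "donor_id": donors,
            "batch_id": batches,
            "sample_id": [f"{d}_{b}" for d, b in zip(donors, batches)],
            # nominal QC columns so the QC stage is exercisable end to end
            "umi_count": rng.integers(900, 20000, size=n_cells),
            "mito_fraction": rng.beta(2, 40, size=n_cells),
            "doublet_flag": rng.random(n_cells) < 0.02,
        }
    )

    label_layers = []
    for lvl in range(depth):
        label_layers.append(np.array(["/".join(map(str, p[: lvl + 1])) for p in paths], dtype=object)[leaf_of_cell])
    truth = ClusterTree.from_labels(label_layers, cell_ids, embedding=embedding)
    for lvl in range(depth):
        cells[f"true_C{lvl}"] = truth.labels_at_level(lvl)
    return embedding, cells, truth


# ---------------------------------------------------------------------------
# counts
# ---------------------------------------------------------------------------


def simulate_counts(
    truth: ClusterTree,
    cells: pd.DataFrame,
    n_genes: int = 1000,
    markers_per_leaf: int = 5,
    batch_effect_sd: float = 0.2,
    seed: int = 0,
    marker_fold: float = 10.0,
    base_mean: float = 0.5,
    depth_sd: float = 0.3,
    dispersion: float = 0.3,
):
    """Gamma-Poisson counts with planted leaf markers and batch factors.

    Each leaf of ``truth`` receives ``markers_per_leaf`` dedicated genes whose
    mean is ``marker_fold`` times elevated in that leaf only.  Batch effects
    are multiplicative log-normal per-(batch, gene) factors; per-cell depth
    factors are log-normal.  Any cell that would end up with zero total counts
    gets a single pseudo-count in its first gene so library sizes stay
    positive.

    Returns ``(counts, marker_genes)`` where ``marker_genes`` maps leaf node
    id -> list of planted marker gene ids.
    """
    rng = np.random.default_rng(seed)
    leaf_level = truth.n_levels - 1
    leaves = truth.nodes_at_level(leaf_level)
    n_leaves = len(leaves)
    require(markers_per_leaf >= 0, "markers_per_leaf must be >= 0")
    if markers_per_leaf * n_leaves > n_genes:
        raise ValidationError(
            f"markers_per_leaf * leaves = {markers_per_leaf * n_leaves} exceeds n_genes = {n_genes}"
        )
    require(len(cells) == truth.n_cells, "cell table does not match truth tree")

    n_cells = truth.n_cells
    genes = np.array([f"gene{g:05d}" for g in range(n_genes)], dtype=object)
    lam = base_mean * rng.lognormal(0.0, 0.5, size=n_genes)

    leaf_label = truth.labels_at_level(leaf_level)
    fold = np.ones((n_leaves, n_genes))
    marker_genes: dict[str, list[str]] = {}
    next_gene = 0
    for li, leaf in enumerate(leaves):
        gs = list(range(next_gene, next_gene + markers_per_leaf))
        next_gene += markers_per_leaf
        fold[li, gs] = marker_fold
        marker_genes[leaf.id] = [genes[g] for g in gs]

    batch_values = sorted(set(cells["batch_id"]))
    batch_factor = rng.lognormal(0.0, batch_effect_sd, size=(len(batch_values), n_genes))
    batch_idx = np.array([batch_values.index(b) for b in cells["batch_id"]])
    leaf_ids = [leaf.id for leaf in leaves]
    leaf_idx = np.array([leaf_ids.index(l) for l in leaf_label])
    depth_factor = rng.lognormal(0.0, depth_sd, size=n_cells)

    mu = depth_factor[:, None] * lam[None, :] * fold[leaf_idx] * batch_factor[batch_idx]
    gamma = rng.gamma(shape=1.0 / dispersion, scale=dispersion, size=mu.shape)
    x = rng.poisson(mu * gamma).astype(np.int64)
    empty = x.sum(axis=1) == 0
    x[empty, 0] += 1

    counts = CountMatrix(sp.csr_matrix(x), genes, cells["cell_id"].to_numpy())
    return counts, marker_genes


# ---------------------------------------------------------------------------
# species pair
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class SpeciesPairSpec:
    """Two species sharing a subset of clusters in a joint embedding.

    Shared clusters get correlated centroids: species B's centroid is species
    A's plus isotropic noise of scale ``divergence_sd`` (centroid coordinates
    are standard normal, so the expected centroid correlation of a true pair
    is 1/sqrt(1 + divergence_sd^2); the default plants r ~= 0.9).
    ``one_to_two`` shared clusters additionally map to a second species-B
    cluster (planted 1:N relations).
    """

    shared_leaves: int = 20
    a_only_leaves: int = 5
    b_only_leaves: int = 5
    divergence_sd: float = 0.4843
    homolog_fraction: float = 0.9
    one_to_two: int = 0
    embedding_dim: int = 50
    cells_per_leaf: int = 80
    noise_sd: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        require(self.shared_leaves + self.a_only_leaves > 0, "species A needs at least one cluster")
        require(self.shared_leaves + self.b_only_leaves > 0, "species B needs at least one cluster")
        require(self.divergence_sd >= 0, "divergence_sd must be nonnegative")
        if not 0 <= self.homolog_fraction <= 1:
            raise ValidationError("homolog_fraction must be in [0, 1]")
        require(0 <= self.one_to_two <= self.shared_leaves, "one_to_two must be <= shared_leaves")
        require(self.embedding_dim >= 3, "embedding_dim must be >= 3")


def simulate_species_pair(spec: SpeciesPairSpec):
    """Joint embedding with matched clusters across two species.

    Returns ``(embedding, species, labels, truth)``: the joint embedding
    (all cells of both species), a per-cell species tag ("A"/"B"), per-cell
    cluster labels ("A0".., "B0"..) and the truth match table with columns
    ``cluster_a, cluster_b, relation``.
    """
    rng = np.random.default_rng(spec.seed)
    d = spec.embedding_dim

    shared = rng.normal(size=(spec.shared_leaves, d))
    cent_a = [shared[i] for i in range(spec.shared_leaves)]
    cent_a += [rng.normal(size=d) for _ in range(spec.a_only_leaves)]
    cent_b = [
        shared[i] + rng.normal(scale=spec.divergence_sd, size=d)
        for i in range(spec.shared_leaves)
    ]
    truth_rows = [
        {"cluster_a": f"A{i}", "cluster_b": f"B{i}", "relation": "1:1"}
        for i in range(spec.shared_leaves)
    ]
    for j in range(spec.one_to_two):
        extra = len(cent_b)
        cent_b.append(shared[j] + rng.normal(scale=spec.divergence_sd, size=d))
        truth_rows.append({"cluster_a": f"A{j}", "cluster_b": f"B{extra}", "relation": "1:N"})
        truth_rows[j]["relation"] = "1:N"
    cent_b += [rng.normal(size=d) for _ in range(spec.b_only_leaves)]

    def _cells(centroids, tag):
        emb, lab = [], []
        for i, c in enumerate(centroids):
            emb.append(c + rng.normal(scale=spec.noise_sd, size=(spec.cells_per_leaf, d)))
            lab += [f"{tag}{i}"] * spec.cells_per_leaf
        return np.vstack(emb), np.array(lab, dtype=object)

    emb_a, lab_a = _cells(cent_a, "A")
    emb_b, lab_b = _cells(cent_b, "B")
    embedding = np.vstack([emb_a, emb_b])
    species = np.array(["A"] * len(lab_a) + ["B"] * len(lab_b), dtype=object)
    labels = np.concatenate([lab_a, lab_b])
    truth = pd.DataFrame(truth_rows, columns=["cluster_a", "cluster_b", "relation"])
    return embedding, species, labels, truth


def simulate_homology_table(
    n_genes: int = 100,
    homolog_fraction: float = 0.9,
    duplicate_fraction: float = 0.1,
    seed: int = 0,
) -> pd.DataFrame:
    """Gene homology table with a controllable share of 1:N relationships."""
    rng = np.random.default_rng(seed)
    rows = []
    for g in range(n_genes):
        if rng.random() > homolog_fraction:
            continue
        ga, gb = f"ga{g:04d}", f"gb{g:04d}"
        rows.append({"gene_a": ga, "gene_b": gb, "similarity": float(rng.uniform(60, 100))})
        if rng.random() < duplicate_fraction:
            rows.append(
                {"gene_a": ga, "gene_b": f"gb{g:04d}x", "similarity": float(rng.uniform(40, 100))}
            )
    return pd.DataFrame(rows, columns=["gene_a", "gene_b", "similarity"])


# ---------------------------------------------------------------------------
# spatial
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class SpatialSpec:
    """Planted spot x cluster abundance maps.

    ``affinity`` (clusters x regions) is each cluster's expected abundance
    profile across regions; spot abundances are the affinity of the spot's
    region plus Gaussian noise, clipped at zero.  Clusters with a flat
    affinity row are planted as unassignable ("NA").
    """

    n_regions: int
    spots_per_region: int
    n_clusters: int
    affinity: tuple  # nested tuple, clusters x regions
    noise_sd: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        require(self.n_regions > 0 and self.spots_per_region > 0 and self.n_clusters > 0,
                "dimensions must be positive")
        aff = np.asarray(self.affinity, dtype=float)
        require(aff.shape == (self.n_clusters, self.n_regions), "affinity must be clusters x regions")
        require((aff >= 0).all(), "affinity must be nonnegative")
        require(self.noise_sd > 0, "noise_sd must be positive")


def planted_affinity(
    n_regions: int,
    n_planted: int,
    n_flat: int,
    signal: float = 10.0,
    baseline: float = 1.0,
) -> np.ndarray:
    """Affinity matrix with ``n_planted`` one-region clusters and ``n_flat`` flat ones."""
    aff = np.full((n_planted + n_flat, n_regions), baseline)
    for c in range(n_planted):
        aff[c, c % n_regions] = signal
    return aff


def simulate_spatial(spec: SpatialSpec):
    """Abundance matrix, true region labels and true cluster -> region map.

    Returns ``(abundance, region_labels, truth_map)``: a spots x clusters
    DataFrame, a spot -> region Series and a dict mapping cluster id to its
    planted region (or ``None`` for flat-affinity clusters).
    """
    rng = np.random.default_rng(spec.seed)
    aff = np.asarray(spec.affinity, dtype=float)
    n_spots = spec.n_regions * spec.spots_per_region
    region_of_spot = np.repeat(np.arange(spec.n_regions), spec.spots_per_region)

    expected = aff[:, region_of_spot].T  # spots x clusters
    abundance = np.clip(expected + rng.normal(scale=spec.noise_sd, size=expected.shape), 0.0, None)

    spot_ids = [f"spot{i:05d}" for i in range(n_spots)]
    cluster_ids = [f"K{c}" for c in range(spec.n_clusters)]
    region_ids = [f"R{r}" for r in range(spec.n_regions)]
    abundance_df = pd.DataFrame(abundance, index=spot_ids, columns=cluster_ids)
    labels = pd.Series([region_ids[r] for r in region_of_spot], index=spot_ids, name="region")

    truth_map: dict[str, str | None] = {}
    for c in range(spec.n_clusters):
        row = aff[c]
        if np.ptp(row) == 0 or (row == row.max()).sum() > 1:
            truth_map[cluster_ids[c]] = None
        else:
            truth_map[cluster_ids[c]] = region_ids[int(row.argmax())]
    return abundance_df, labels, truth_map


# ---------------------------------------------------------------------------
# GWAS tables
# ---------------------------------------------------------------------------


def simulate_gwas_tables(
    n_genes: int,
    n_celltypes: int,
    planted_effectors,
    seed: int = 0,
    top_n: int = 1000,
    zero_fraction: float = 0.3,
):
    """Specificity matrix and gene-rank table with planted effector genes.

    Planted effectors receive a specificity of 0.9-1.0 in one to three cell
    types (background values stay below 0.8, so planted genes exceed any
    per-cell-type 95th-percentile cutoff) and an association rank <= ``top_n``.
    The remaining top-``top_n`` ranks go to genes with all-zero specificity,
    so every non-planted gene fails at least one selection criterion by
    construction.

    ``planted_effectors`` may be an integer count or an iterable of gene ids
    of the form ``G%05d``.  Returns ``(specificity, ranks)`` with ranks a
    permutation of 1..n_genes.
    """
    rng = np.random.default_rng(seed)
    genes = np.array([f"G{g:05d}" for g in range(n_genes)], dtype=object)
    if isinstance(planted_effectors, (int, np.integer)):
        planted = list(rng.choice(genes, size=int(planted_effectors), replace=False))
    else:
        planted = sorted(set(planted_effectors))
        unknown = set(planted) - set(genes)
        if unknown:
            raise ValidationError(f"planted effectors not in gene universe: {sorted(unknown)[:5]}")
    n_planted = len(planted)
    require(n_planted <= top_n, "cannot plant more effectors than top-ranked genes")
    require(
        top_n <= n_genes // 2,
        "top_n must leave at least half the gene universe as background "
        "(zero-specificity filler genes would otherwise dominate the nonzero percentile)",
    )
    # keep planted values rare enough that they sit above every per-cell-type
    # 95th percentile of nonzero values
    require(
        3 * max(n_planted, 1) <= 0.04 * n_genes * n_celltypes * (1 - zero_fraction) or n_planted == 0,
        "too many planted effectors for the gene universe",
    )

    spec = rng.uniform(0.0, 0.8, size=(n_genes, n_celltypes))
    spec[rng.random((n_genes, n_celltypes)) < zero_fraction] = 0.0

    gene_pos = {g: i for i, g in enumerate(genes)}
    celltypes = np.array([f"CT{c}" for c in range(n_celltypes)], dtype=object)
    planted_idx = np.array([gene_pos[g] for g in planted], dtype=int)
    for gi in planted_idx:
        hit = rng.choice(n_celltypes, size=int(rng.integers(1, 4)), replace=False)
        spec[gi, hit] = rng.uniform(0.9, 1.0, size=len(hit))

    # non-planted genes inside the top ranks must fail specificity everywhere
    others = np.setdiff1d(np.arange(n_genes), planted_idx)
    filler = rng.choice(others, size=top_n - n_planted, replace=False)
    spec[filler] = 0.0

    top_block = np.concatenate([planted_idx, filler])
    rng.shuffle(top_block)
    rest = np.setdiff1d(np.arange(n_genes), top_block)
    rng.shuffle(rest)
    order = np.concatenate([top_block, rest])  # order[i] = gene with rank i+1
    ranks = np.empty(n_genes, dtype=int)
    ranks[order] = np.arange(1, n_genes + 1)

    spec_df = pd.DataFrame(spec, index=genes, columns=celltypes)
    stat = -np.log10(ranks / (n_genes + 1.0))
    rank_df = pd.DataFrame({"gene": genes, "stat": stat, "rank": ranks}).set_index("gene")
    return spec_df, rank_df
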