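"""GWAS cell-type prioritization and effector-gene selection.

Cell-type specificity matrices (any CELLEX-style score in [0, 1]) are
aggregated by bootstrapping the dataset into random cell subsets and averaging
the per-subset matrices.  Effector genes are the intersection of two
criteria: specificity above a per-cell-type percentile cutoff in at least one
cell type, and a gene-association rank within the top N.  Bonferroni
thresholds handle cell-type and gene-burden significance calls.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from ._validate import ValidationError, require
from .containers import CountMatrix


@dataclass(frozen=True)
class EffectorConfig:
    specificity_percentile: float = 95.0
    top_n_genes: int = 1000
    n_subsets: int = 10
    subset_size: int = 100_000
    celltype_alpha: float = 0.05
    n_celltypes_tested: int | None = None

    def __post_init__(self) -> None:
        require(0 < self.specificity_percentile < 100, "specificity_percentile must be in (0, 100)")
        require(self.top_n_genes > 0, "top_n_genes must be positive")
        require(self.n_subsets > 0 and self.subset_size > 0, "bootstrap sizes must be positive")
        require(0 < self.celltype_alpha < 1, "celltype_alpha must be in (0, 1)")


def mean_expression_specificity(counts: CountMatrix, labels) -> pd.DataFrame:
    """Simple built-in specificity: cell-type mean / sum of cell-type means.

    Values lie in [0, 1] per gene across cell types (rows of zeros for genes
    expressed nowhere).  Serves as the default pluggable specificity function;
    any external score with the same shape can be substituted.
    """
    labels = np.asarray(labels)
    celltypes = sorted(set(labels), key=str)
    means = np.vstack(
        [np.asarray(counts.matrix[labels == ct].mean(axis=0)).ravel() for ct in celltypes]
    ).T  # genes x celltypes
    totals = means.sum(axis=1, keepdims=True)
    with np.errstate(invalid="ignore", divide="ignore"):
        spec = np.where(totals > 0, means / np.maximum(totals, 1e-300), 0.0)
    return pd.DataFrame(spec, index=counts.genes, columns=celltypes)


def bootstrap_specificity(
    counts: CountMatrix,
    labels,
    spec_fn=None,
    cfg: EffectorConfig | None = None,
    seed: int = 0,
    disjoint: bool = False,
) -> pd.DataFrame:
    """Elementwise mean of a specificity function over random cell subsets.

    ``n_subsets`` subsets of ``subset_size`` cells are drawn without
    replacement within each subset (independently across subsets by default;
    ``disjoint`` partitions the cells instead).  Genes or cell types absent
    from a subset's result contribute 0 to the mean, with a warning.
    """
    cfg = cfg or EffectorConfig()
    spec_fn = spec_fn or mean_expression_specificity
    labels = np.asarray(labels)
    n = counts.n_cells
    require(cfg.subset_size <= n, "subset_size exceeds the number of cells")
    if disjoint:
        require(cfg.n_subsets * cfg.subset_size <= n, "disjoint subsets exceed the dataset")
    rng = np.random.default_rng(seed)

    if disjoint:
        perm = rng.permutation(n)
        subsets = [
            perm[i * cfg.subset_size : (i + 1) * cfg.subset_size]
            for i in range(cfg.n_subsets)
        ]
    else:
        subsets = [rng.choice(n, size=cfg.subset_size, replace=False) for _ in range(cfg.n_subsets)]

    results = []
    for rows in subsets:
        rows = np.sort(rows)
        mat = spec_fn(counts.subset_cells(rows), labels[rows])
        vals = mat.to_numpy(dtype=float)
        if np.nanmin(vals) < 0 or np.nanmax(vals) > 1:
            raise ValidationError("specificity function returned values outside [0, 1]")
        results.append(mat)

    genes = results[0].index
    celltypes = results[0].columns
    for mat in results[1:]:
        genes = genes.union(mat.index)
        celltypes = celltypes.union(mat.columns)
    aligned = []
    for mat in results:
        if not (mat.index.equals(genes) and mat.columns.equals(celltypes)):
            warnings.warn("genes/cell types absent from a bootstrap subset contribute 0")
        aligned.append(mat.reindex(index=genes, columns=celltypes).fillna(0.0))
    return sum(aligned) / len(aligned)


def prioritize_celltypes(celltype_pvalues: dict, cfg: EffectorConfig | None = None) -> set:
    """Cell types significant at the Bonferroni threshold alpha / n_tested."""
    cfg = cfg or EffectorConfig()
    if not celltype_pvalues:
        return set()
    n_tested = cfg.n_celltypes_tested or len(celltype_pvalues)
    cutoff = cfg.celltype_alpha / n_tested
    return {ct for ct, p in celltype_pvalues.items() if p < cutoff}


def select_effector_genes(
    spec: pd.DataFrame,
    ranks: pd.DataFrame,
    cfg: EffectorConfig | None = None,
    global_percentile: bool = False,
) -> pd.DataFrame:
    """Genes above the specificity percentile in >= 1 cell type and top-ranked.

    The cutoff is the ``specificity_percentile`` of each cell type's *nonzero*
    specificity values (or of the whole matrix with ``global_percentile``),
    computed with linear interpolation; a gene qualifies when it strictly
    exceeds the cutoff somewhere and its association rank is at most
    ``top_n_genes``.  Returns one row per selected gene with its supporting
    cell types.
    """
    cfg = cfg or EffectorConfig()
    if "rank" not in ranks.columns:
        raise ValidationError("rank table must have a 'rank' column")
    shared = spec.index.intersection(ranks.index)
    if shared.empty:
        raise ValidationError("specificity matrix and rank table share no genes")
    spec = spec.loc[shared]
    rank = ranks.loc[shared, "rank"]

    vals = spec.to_numpy(dtype=float)
    if global_percentile:
        nz = vals[vals > 0]
        cutoffs = np.full(vals.shape[1], np.percentile(nz, cfg.specificity_percentile) if nz.size else np.inf)
    else:
        cutoffs = np.array(
            [
                np.percentile(col[col > 0], cfg.specificity_percentile) if (col > 0).any() else np.inf
                for col in vals.T
            ]
        )
    above = vals > cutoffs[None, :]
    in_top = (rank <= cfg.top_n_genes).to_numpy()
    selected = above.any(axis=1) & in_top

    rows = []
    for gi in np.flatnonzero(selected):
        support = [spec.columns[c] for c in np.flatnonzero(above[gi])]
        best = int(np.argmax(vals[gi]))
        rows.append(
            {
                "gene": shared[gi],
                "celltypes": ";".join(map(str, support)),
                "best_celltype": spec.columns[best],
                "specificity": float(vals[gi, best]),
                "rank": int(rank.iloc[gi]),
            }
        )
    return pd.DataFrame(rows, columns=["gene", "celltypes", "best_celltype", "specificity", "rank"])


def prioritize_effector_burden(
    gene_pvalues: dict, n_genes_tested: int, alpha: float = 0.05
) -> set:
    """Genes significant in burden tests at the Bonferroni threshold alpha / n."""
    require(n_genes_tested > 0, "n_genes_tested must be positive")
    cutoff = alpha / n_genes_tested
    return {g for g, p in gene_pvalues.items() if p < cutoff}
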