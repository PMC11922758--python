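"""Batch-stratified differential expression via a van Elteren rank-sum test.

Marker genes are scored with a stratified Wilcoxon rank-sum test: within each
batch (stratum) the usual rank-sum statistic is computed, strata are combined
with the locally-best van Elteren weights 1/(n1+n2+1), and the combined
statistic is referred to a standard normal.  P values are Bonferroni-corrected
over the number of genes tested.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import scipy.sparse as sp
from scipy import stats

from ._validate import ValidationError
from .containers import CountMatrix

_LFC_EPS = 1e-9


def _rank_columns(x: np.ndarray) -> np.ndarray:
    """Average ranks per column (ties shared), ranks starting at 1."""
    return stats.rankdata(x, axis=0)


def _tie_term(x: np.ndarray) -> np.ndarray:
    """Per-column sum of t^3 - t over tie groups (for rank-sum variance)."""
    n, g = x.shape
    xs = np.sort(x, axis=0)
    # group id of each sorted entry within its column
    new_group = np.vstack([np.ones((1, g), dtype=bool), xs[1:] != xs[:-1]])
    group_ids = np.cumsum(new_group, axis=0) - 1  # 0-based per column
    flat = group_ids + np.arange(g) * n  # disjoint id space per column
    sizes = np.bincount(flat.ravel(), minlength=g * n).reshape(g, n)
    return (sizes.astype(float) ** 3 - sizes).sum(axis=1)


def stratified_rank_sum(
    x, in_target: np.ndarray, strata: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Stratified two-sided rank-sum test for every column of ``x``.

    Parameters
    ----------
    x:
        cells x genes matrix (dense or sparse).
    in_target:
        Boolean mask of target-group cells.
    strata:
        Per-cell stratum labels (e.g. batch).  Strata without at least one
        cell on each side are dropped; if all strata are dropped a
        :class:`ValidationError` is raised.

    Returns
    -------
    z, p:
        Combined standardized statistic and two-sided normal p value per gene.
    """
    in_target = np.asarray(in_target, dtype=bool)
    strata = np.asarray(strata)
    if sp.issparse(x):
        x = np.asarray(x.todense())
    x = np.asarray(x, dtype=float)
    n_genes = x.shape[1]

    t_num = np.zeros(n_genes)
    t_var = np.zeros(n_genes)
    used = 0
    for s in np.unique(strata):
        rows = strata == s
        tgt = in_target[rows]
        n1 = int(tgt.sum())
        n2 = int((~tgt).sum())
        if n1 == 0 or n2 == 0:
            continue
        used += 1
        n = n1 + n2
        ranks = _rank_columns(x[rows])
        w_stat = ranks[tgt].sum(axis=0)
        expect = n1 * (n + 1) / 2.0
        ties = _tie_term(x[rows])
        var = n1 * n2 / 12.0 * ((n + 1) - ties / (n * (n - 1)))
        weight = 1.0 / (n + 1)
        t_num += weight * (w_stat - expect)
        t_var += weight**2 * var
    if used == 0:
        raise ValidationError("no comparable stratum: every stratum lacks target or background cells")

    z = np.zeros(n_genes)
    ok = t_var > 0
    z[ok] = t_num[ok] / np.sqrt(t_var[ok])
    p = 2.0 * stats.norm.sf(np.abs(z))
    return z, np.minimum(p, 1.0)


def find_markers(
    counts: CountMatrix,
    labels: np.ndarray,
    batch: np.ndarray,
    target,
    background="all_other",
) -> pd.DataFrame:
    """Marker genes of ``target`` versus a background set of clusters.

    Parameters
    ----------
    counts:
        Count matrix aligned with ``labels`` and ``batch``.
    labels:
        Per-cell cluster labels.
    batch:
        Per-cell batch (stratification variable).
    target:
        Cluster id whose markers are sought.
    background:
        ``"all_other"`` or an explicit collection of cluster ids
        (e.g. the target's siblings in a cluster tree).

    Returns
    -------
    DataFrame with one row per gene: z statistic, raw and Bonferroni-adjusted
    p value, log2 fold-change and detection-rate difference.
    """
    labels = np.asarray(labels)
    batch = np.asarray(batch)
    if labels.shape[0] != counts.n_cells or batch.shape[0] != counts.n_cells:
        raise ValidationError("labels/batch length does not match count matrix")
    tgt_mask = labels == target
    if not tgt_mask.any():
        raise ValidationError(f"target cluster {target!r} is empty")
    if isinstance(background, str) and background == "all_other":
        bg_mask = ~tgt_mask
        comparison = "vs_all"
    else:
        bg_mask = np.isin(labels, list(background)) & ~tgt_mask
        comparison = "vs_sibling"
    if not bg_mask.any():
        raise ValidationError("background set is empty")

    keep = tgt_mask | bg_mask
    sub = counts.matrix[keep]
    z, p = stratified_rank_sum(sub, tgt_mask[keep], batch[keep])

    n_genes = counts.n_genes
    padj = np.minimum(p * n_genes, 1.0)

    mean_t = np.asarray(counts.matrix[tgt_mask].mean(axis=0)).ravel()
    mean_b = np.asarray(counts.matrix[bg_mask].mean(axis=0)).ravel()
    lfc = np.log2((mean_t + _LFC_EPS) / (mean_b + _LFC_EPS))
    det_t = np.asarray((counts.matrix[tgt_mask] > 0).mean(axis=0)).ravel()
    det_b = np.asarray((counts.matrix[bg_mask] > 0).mean(axis=0)).ravel()

    return pd.DataFrame(
        {
            "gene": counts.genes,
            "cluster": target,
            "comparison": comparison,
            "z": z,
            "pval": p,
            "padj": padj,
            "lfc": lfc,
            "detection_diff": det_t - det_b,
        }
    )


def count_strong_markers(
    marker_table: pd.DataFrame, alpha: float = 0.05, min_lfc: float = 0.5
) -> int:
    """Number of "strong" markers: Bonferroni-significant and up-regulated."""
    strong = (marker_table["padj"] < alpha) & (marker_table["lfc"] >= min_lfc)
    return int(strong.sum())
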