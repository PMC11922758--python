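"""Cross-species cluster matching.

Clusters of two species are matched through their centroids in a joint
embedding: Pearson correlations between centroid vectors are computed for all
cross-species cluster pairs, penalized relative to each row/column maximum
("adjusted correlation"), thresholded into a bipartite graph, and the graph is
pruned until every connected component is a star — yielding 1:1, 1:N and M:1
relationships.
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd

from ._validate import ValidationError, require, require_columns


@dataclass(frozen=True)
class MatchConfig:
    adjusted_threshold: float = 0.7
    hvg_per_species: int = 2500

    def __post_init__(self) -> None:
        require(-1 < self.adjusted_threshold < 1, "adjusted_threshold must be in (-1, 1)")
        require(self.hvg_per_species > 0, "hvg_per_species must be positive")


# ---------------------------------------------------------------------------
# gene-level preprocessing
# ---------------------------------------------------------------------------


def reduce_homologs(table: pd.DataFrame) -> pd.DataFrame:
    """Reduce a homology table to a one-to-one gene map.

    Pairs are admitted greedily in order of decreasing similarity; a pair is
    kept only if neither of its genes already belongs to a kept pair, so each
    gene retains only its highest-similarity partner.  Ties are broken by the
    lexicographically smaller gene ids.
    """
    require_columns(table, ["gene_a", "gene_b", "similarity"], "homology table")
    require(len(table) > 0, "homology table is empty")
    if table.duplicated(["gene_a", "gene_b"]).any():
        raise ValidationError("homology table contains duplicate gene pairs")
    ordered = table.sort_values(
        ["similarity", "gene_a", "gene_b"], ascending=[False, True, True]
    )
    used_a: set = set()
    used_b: set = set()
    keep = []
    for row in ordered.itertuples(index=True):
        if row.gene_a in used_a or row.gene_b in used_b:
            continue
        used_a.add(row.gene_a)
        used_b.add(row.gene_b)
        keep.append(row.Index)
    return table.loc[sorted(keep)].reset_index(drop=True)


def select_shared_hvgs(
    flags_a: pd.DataFrame,
    flags_b: pd.DataFrame,
    cfg: MatchConfig | None = None,
    variances_a: pd.Series | None = None,
    variances_b: pd.Series | None = None,
) -> list:
    """Shared highly variable genes across species.

    ``flags_a``/``flags_b`` are boolean genes x samples (or genes x batches)
    matrices marking per-sample HVG calls.  Genes are ranked per species by
    the number of samples flagging them; the top ``hvg_per_species`` are taken
    and the intersection returned.  Rank ties at the cutoff are resolved by
    mean per-sample variance (when provided), then by gene id.
    """
    cfg = cfg or MatchConfig()

    def _top(flags: pd.DataFrame, variances: pd.Series | None) -> set:
        occurrence = flags.sum(axis=1)
        if variances is not None:
            secondary = variances.reindex(flags.index).fillna(0.0)
        else:
            secondary = pd.Series(0.0, index=flags.index)
        ranked = pd.DataFrame({"occ": occurrence, "var": secondary})
        ranked = ranked.loc[ranked.index.sort_values()]  # gene id as final tie-break
        ranked = ranked.sort_values(["occ", "var"], ascending=False, kind="mergesort")
        return set(ranked.index[: cfg.hvg_per_species])

    shared = sorted(_top(flags_a, variances_a) & _top(flags_b, variances_b))
    if not shared:
        raise ValidationError(
            "no shared HVGs; lower hvg_per_species stringency or check the homolog map"
        )
    return shared


# ---------------------------------------------------------------------------
# centroid correlation and adjustment
# ---------------------------------------------------------------------------


def correlate_centroids(
    joint_embedding: np.ndarray, labels_a: pd.Series, labels_b: pd.Series
) -> pd.DataFrame:
    """Pearson correlation between cluster centroids of two species.

    ``labels_a`` and ``labels_b`` map row indices of the joint embedding to
    cluster ids for the cells of each species.  The centroid of a cluster is
    the mean embedding vector of its cells; entry (i, j) is the Pearson r of
    centroid_i (species A) and centroid_j (species B) across embedding
    dimensions.
    """
    emb = np.asarray(joint_embedding, dtype=float)
    if emb.shape[1] < 3:
        raise ValidationError("embedding dimension must be >= 3 for centroid correlation")

    def _centroids(labels: pd.Series) -> pd.DataFrame:
        groups = {}
        for cl in sorted(set(labels.values), key=str):
            rows = labels.index[labels.values == cl]
            groups[cl] = emb[np.asarray(rows, dtype=int)].mean(axis=0)
        return pd.DataFrame(groups).T

    cent_a = _centroids(pd.Series(labels_a))
    cent_b = _centroids(pd.Series(labels_b))
    a = cent_a.to_numpy()
    b = cent_b.to_numpy()
    a_c = a - a.mean(axis=1, keepdims=True)
    b_c = b - b.mean(axis=1, keepdims=True)
    a_n = a_c / np.linalg.norm(a_c, axis=1, keepdims=True)
    b_n = b_c / np.linalg.norm(b_c, axis=1, keepdims=True)
    return pd.DataFrame(a_n @ b_n.T, index=cent_a.index, columns=cent_b.index)


def adjust_correlations(corr: pd.DataFrame, mode: str = "both") -> pd.DataFrame:
    """Penalize correlations by their distance to the row/column maximum.

    For entry r with row maximum M_row and column maximum M_col the one-sided
    adjustments are ``2 r - M_row`` and ``2 r - M_col`` (the gap to the
    maximum is subtracted from the value itself).  ``mode`` selects the row
    adjustment, the column adjustment, or their minimum (default), which makes
    the downstream threshold symmetric in both species.  Entries that are both
    their row and column maximum are unchanged.
    """
    values = corr.to_numpy(dtype=float)
    if not np.isfinite(values).all():
        raise ValidationError("correlation matrix contains non-finite entries")
    row_adj = 2 * values - values.max(axis=1, keepdims=True)
    col_adj = 2 * values - values.max(axis=0, keepdims=True)
    if mode == "row":
        adj = row_adj
    elif mode == "col":
        adj = col_adj
    elif mode == "both":
        adj = np.minimum(row_adj, col_adj)
    else:
        raise ValidationError(f"unknown adjustment mode {mode!r}")
    return pd.DataFrame(adj, index=corr.index, columns=corr.columns)


# ---------------------------------------------------------------------------
# match graph
# ---------------------------------------------------------------------------


def _node(species: str, cluster) -> tuple:
    return (species, cluster)


def build_match_graph(
    adjusted: pd.DataFrame,
    cfg: MatchConfig | None = None,
    raw: pd.DataFrame | None = None,
) -> nx.Graph:
    """Bipartite cluster graph with edges where adjusted correlation > threshold.

    All clusters of both species appear as nodes (degree 0 means unmatched);
    each edge stores the adjusted and, when available, the raw correlation.
    """
    cfg = cfg or MatchConfig()
    graph = nx.Graph()
    for cl in adjusted.index:
        graph.add_node(_node("A", cl), species="A")
    for cl in adjusted.columns:
        graph.add_node(_node("B", cl), species="B")
    for i, cl_a in enumerate(adjusted.index):
        for j, cl_b in enumerate(adjusted.columns):
            val = float(adjusted.iat[i, j])
            if val > cfg.adjusted_threshold:
                graph.add_edge(
                    _node("A", cl_a),
                    _node("B", cl_b),
                    adjusted=val,
                    raw=float(raw.iat[i, j]) if raw is not None else np.nan,
                )
    return graph


def prune_match_graph(graph: nx.Graph, single_pass: bool = False) -> nx.Graph:
    """Remove M:N relationships so every component becomes a star.

    Nodes are visited in deterministic (species, cluster id) order; a node
    whose neighbourhood contains another node of degree >= 2 keeps only its
    maximum-adjusted-correlation edge (ties broken by partner id).  By default
    sweeps repeat until a fixed point; ``single_pass`` stops after one sweep.
    Edges are annotated with a ``relation`` of 1:1, 1:N or M:1 afterwards.
    """
    out = graph.copy()
    order = sorted(out.nodes, key=lambda n: (n[0], str(n[1])))
    while True:
        changed = False
        for node in order:
            if node not in out or out.degree(node) == 0:
                continue
            neighbours = list(out.neighbors(node))
            if not any(out.degree(v) >= 2 for v in neighbours):
                continue
            best = min(
                neighbours,
                key=lambda v: (-out.edges[node, v]["adjusted"], v[0], str(v[1])),
            )
            drop = [v for v in neighbours if v != best]
            if drop:
                out.remove_edges_from((node, v) for v in drop)
                changed = True
        if single_pass or not changed:
            break
    _annotate_relations(out)
    return out


def _annotate_relations(graph: nx.Graph) -> None:
    for component in nx.connected_components(graph):
        edges = list(graph.subgraph(component).edges)
        if not edges:
            continue
        if len(edges) == 1:
            relation = "1:1"
        else:
            centers = [n for n in component if graph.degree(n) > 1]
            relation = "1:N" if centers and centers[0][0] == "A" else "M:1"
        for u, v in edges:
            graph.edges[u, v]["relation"] = relation


def match_summary(
    graph: nx.Graph, clusters_a=None, clusters_b=None
) -> pd.DataFrame:
    """One row per cluster of either species: partners, relation, unmatched flag.

    Partners are ordered by descending raw correlation (falling back to the
    adjusted value when no raw correlation was stored).
    """
    rows = []
    known = {n for n in graph.nodes}
    extra = [("A", c) for c in (clusters_a if clusters_a is not None else [])]
    extra += [("B", c) for c in (clusters_b if clusters_b is not None else [])]
    all_nodes = sorted(known | set(extra), key=lambda n: (n[0], str(n[1])))
    for node in all_nodes:
        if node in known and graph.degree(node) > 0:
            nbrs = list(graph.neighbors(node))

            def _key(v):
                data = graph.edges[node, v]
                r = data.get("raw")
                return data["adjusted"] if r is None or np.isnan(r) else r

            nbrs.sort(key=_key, reverse=True)
            relation = graph.edges[node, nbrs[0]].get("relation", "1:1")
            partners = ";".join(str(v[1]) for v in nbrs)
            unmatched = False
        else:
            partners, relation, unmatched = "", "unmatched", True
        rows.append(
            {
                "species": node[0],
                "cluster": node[1],
                "partners": partners,
                "relation": relation,
                "unmatched": unmatched,
            }
        )
    return pd.DataFrame(rows)
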