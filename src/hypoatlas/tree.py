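"""Multi-level cluster hierarchies: reconciliation of flat consensus layers
into a strictly nested tree, and marker-based iterative pruning.

The tree levels are named ``C0`` (coarsest) to ``C{L-1}`` (finest), mirroring
the convention of multi-level cell-type taxonomies; a virtual ``root`` node
sits above the ``C0`` classes.
"""

from __future__ import annotations

import copy as _copy
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ._validate import ValidationError, require
from .containers import CountMatrix
from .markers import count_strong_markers, find_markers

ROOT = "root"


@dataclass
class TreeNode:
    id: str
    level: int  # -1 for the virtual root
    parent: str | None
    children: list[str] = field(default_factory=list)
    cells: np.ndarray = field(default_factory=lambda: np.array([], dtype=int))
    centroid: np.ndarray | None = None


@dataclass
class PruneConfig:
    """Criteria for merging under-supported tree nodes into siblings."""

    min_strong_markers: int = 5
    min_cells: int = 50
    max_single_donor_fraction: float = 0.90
    n_iterations: int = 5
    strong_marker_alpha: float = 0.05
    strong_marker_min_lfc: float = 0.5

    def __post_init__(self) -> None:
        require(self.min_strong_markers >= 0, "min_strong_markers must be >= 0")
        require(self.min_cells > 0, "min_cells must be positive")
        require(
            0 < self.max_single_donor_fraction <= 1,
            "max_single_donor_fraction must be in (0, 1]",
        )
        require(self.n_iterations > 0, "n_iterations must be positive")


class ClusterTree:
    """Strictly nested multi-level clustering of a fixed set of cells."""

    def __init__(self, nodes: dict[str, TreeNode], cell_ids) -> None:
        self.nodes = nodes
        self.cell_ids = np.asarray(cell_ids, dtype=object)
        self.reconciliation_cost: int = 0
        self.prune_log: list[dict] = []

    # -- construction -----------------------------------------------------
    @classmethod
    def from_labels(
        cls,
        labels,
        cell_ids,
        embedding: np.ndarray | None = None,
        level_prefix: str = "C",
    ) -> "ClusterTree":
        """Build a tree from per-level flat labelings (coarse -> fine).

        ``labels`` is a cells x levels array (or list of per-level label
        vectors).  The labelings must already be strictly nested: every fine
        cluster's cells must carry a single coarse label.
        """
        if isinstance(labels, np.ndarray) and labels.ndim == 2:
            lab = labels.astype(object)
        else:
            lab = np.column_stack([np.asarray(col, dtype=object) for col in labels])
        n_cells, n_levels = lab.shape
        cell_ids = np.asarray(cell_ids, dtype=object)
        require(len(cell_ids) == n_cells, "cell_ids length does not match labelings")

        nodes: dict[str, TreeNode] = {ROOT: TreeNode(ROOT, -1, None)}
        node_of: list[dict] = []  # per level: raw label -> node id
        for lvl in range(n_levels):
            uniq = sorted(set(lab[:, lvl]), key=str)
            mapping = {}
            for j, raw in enumerate(uniq):
                nid = f"{level_prefix}{lvl}-{j}"
                cells = np.flatnonzero(lab[:, lvl] == raw)
                if lvl == 0:
                    parent = ROOT
                else:
                    parents = set(lab[cells, lvl - 1])
                    if len(parents) != 1:
                        raise ValidationError(
                            f"labelings are not nested: level-{lvl} cluster {raw!r} "
                            f"spans {len(parents)} level-{lvl - 1} clusters"
                        )
                    parent = node_of[lvl - 1][parents.pop()]
                node = TreeNode(nid, lvl, parent, [], cells)
                if embedding is not None:
                    node.centroid = np.asarray(embedding)[cells].mean(axis=0)
                nodes[nid] = node
                nodes[parent].children.append(nid)
                mapping[raw] = nid
            node_of.append(mapping)
        tree = cls(nodes, cell_ids)
        tree.validate_nested()
        return tree

    # -- queries ----------------------------------------------------------
    @property
    def n_levels(self) -> int:
        return 1 + max((n.level for n in self.nodes.values()), default=-1)

    @property
    def n_cells(self) -> int:
        return len(self.cell_ids)

    def nodes_at_level(self, level: int) -> list[TreeNode]:
        return sorted(
            (n for n in self.nodes.values() if n.level == level), key=lambda n: n.id
        )

    def labels_at_level(self, level: int) -> np.ndarray:
        out = np.empty(self.n_cells, dtype=object)
        for node in self.nodes_at_level(level):
            out[node.cells] = node.id
        if (out == None).any():  # noqa: E711 - object array
            raise ValidationError(f"level {level} does not cover all cells")
        return out

    def siblings(self, node_id: str) -> list[str]:
        node = self.nodes[node_id]
        if node.parent is None:
            return []
        return [c for c in self.nodes[node.parent].children if c != node_id]

    def validate_nested(self) -> None:
        """Children partition the parent's cell set; every level covers all cells."""
        for node in self.nodes.values():
            if not node.children:
                continue
            child_cells = np.concatenate(
                [self.nodes[c].cells for c in node.children]
            )
            if len(child_cells) != len(set(child_cells.tolist())):
                raise ValidationError(f"children of {node.id} overlap")
            parent_cells = (
                np.arange(self.n_cells) if node.id == ROOT else node.cells
            )
            if set(child_cells.tolist()) != set(parent_cells.tolist()):
                raise ValidationError(
                    f"children of {node.id} do not partition its cell set"
                )

    def copy(self) -> "ClusterTree":
        return _copy.deepcopy(self)

    # -- serialization ----------------------------------------------------
    def to_dict(self) -> dict:
        return {
            "cell_ids": self.cell_ids.tolist(),
            "reconciliation_cost": self.reconciliation_cost,
            "nodes": [
                {
                    "id": n.id,
                    "level": n.level,
                    "parent": n.parent,
                    "children": list(n.children),
                    "cells": n.cells.tolist(),
                    "centroid": None if n.centroid is None else list(map(float, n.centroid)),
                }
                for n in sorted(self.nodes.values(), key=lambda n: (n.level, n.id))
            ],
        }

    @classmethod
    def from_dict(cls, payload: dict) -> "ClusterTree":
        nodes = {}
        for rec in payload["nodes"]:
            nodes[rec["id"]] = TreeNode(
                rec["id"],
                rec["level"],
                rec["parent"],
                list(rec["children"]),
                np.asarray(rec["cells"], dtype=int),
                None if rec.get("centroid") is None else np.asarray(rec["centroid"]),
            )
        tree = cls(nodes, np.asarray(payload["cell_ids"], dtype=object))
        tree.reconciliation_cost = payload.get("reconciliation_cost", 0)
        return tree


# ---------------------------------------------------------------------------
# tree construction from flat consensus layers
# ---------------------------------------------------------------------------

MAX_RECONCILE_ITERATIONS = 50


def build_tree(
    consensus_per_resolution,
    embedding: np.ndarray | None = None,
    cell_ids=None,
) -> ClusterTree:
    """Reconcile flat labelings at several resolutions into a nested tree.

    ``consensus_per_resolution`` is an ordered mapping resolution -> labels
    (or a plain sequence of label vectors), coarse to fine.  Each fine cluster
    is attached to the coarse cluster holding the plurality of its cells and
    cells violating nestedness are relabeled along the majority path, iterated
    to a fixed point.  The number of relabeled cell entries is recorded on the
    returned tree as ``reconciliation_cost``.
    """
    if isinstance(consensus_per_resolution, dict):
        layers = [np.asarray(v) for v in consensus_per_resolution.values()]
    else:
        layers = [np.asarray(v) for v in consensus_per_resolution]
    require(len(layers) >= 1, "at least one labeling is required")
    n_cells = len(layers[0])
    for lay in layers:
        require(len(lay) == n_cells, "all labelings must cover the same cells")
    if cell_ids is None:
        cell_ids = np.array([f"cell{i}" for i in range(n_cells)], dtype=object)

    layers = [lay.copy() for lay in layers]
    cost = 0
    for _ in range(MAX_RECONCILE_ITERATIONS):
        changed = 0
        # bottom-up: force each coarse layer to be the plurality parent of
        # the layer below it
        for lvl in range(len(layers) - 1, 0, -1):
            fine, coarse = layers[lvl], layers[lvl - 1]
            for value in sorted(set(fine), key=str):
                cells = np.flatnonzero(fine == value)
                parents, counts = np.unique(coarse[cells], return_counts=True)
                order = np.lexsort((np.array([str(p) for p in parents]), -counts))
                winner = parents[order[0]]
                moved = int((coarse[cells] != winner).sum())
                if moved:
                    coarse[cells] = winner
                    changed += moved
        cost += changed
        if changed == 0:
            break
    tree = ClusterTree.from_labels(layers, cell_ids, embedding=embedding)
    tree.reconciliation_cost = cost
    return tree


# ---------------------------------------------------------------------------
# pruning
# ---------------------------------------------------------------------------


def _node_failures(
    tree: ClusterTree,
    node: TreeNode,
    counts: CountMatrix | None,
    donors: np.ndarray,
    batches: np.ndarray,
    cfg: PruneConfig,
) -> list[str]:
    reasons = []
    if len(node.cells) < cfg.min_cells:
        reasons.append("min_cells")
    node_donors = donors[node.cells]
    top = pd.Series(node_donors).value_counts(normalize=True).iloc[0]
    if top > cfg.max_single_donor_fraction:
        reasons.append("single_donor")
    if counts is not None and cfg.min_strong_markers > 0:
        sib = tree.siblings(node.id)
        labels = tree.labels_at_level(node.level)
        table = find_markers(counts, labels, batches, node.id, background=sib)
        n_strong = count_strong_markers(
            table, cfg.strong_marker_alpha, cfg.strong_marker_min_lfc
        )
        if n_strong < cfg.min_strong_markers:
            reasons.append("weak_markers")
    return reasons


def prune_tree(
    tree: ClusterTree,
    counts: CountMatrix | None,
    cells: pd.DataFrame,
    cfg: PruneConfig | None = None,
) -> ClusterTree:
    """Iteratively merge under-supported nodes into their nearest sibling.

    A node fails when it has fewer than ``min_cells`` cells, when more than
    ``max_single_donor_fraction`` of its cells come from one donor, or when it
    has fewer than ``min_strong_markers`` strong marker genes against its
    siblings.  Failing nodes are merged into the sibling with the smallest
    Euclidean centroid distance; the pass is repeated ``n_iterations`` times
    (stopping early at a fixed point).  Nodes without siblings are left in
    place.  Merge events are recorded on the returned tree's ``prune_log``.

    ``counts`` may be ``None`` to skip the marker criterion (e.g. when only
    size/donor pruning is wanted); ``cells`` must provide ``donor_id`` and
    ``batch_id`` columns aligned with the tree's cells.
    """
    cfg = cfg or PruneConfig()
    require(len(cells) == tree.n_cells, "cell table does not match tree")
    donors = cells["donor_id"].to_numpy()
    batches = cells["batch_id"].to_numpy()
    out = tree.copy()
    out.prune_log = []

    for iteration in range(cfg.n_iterations):
        failing: list[tuple[int, str, list[str]]] = []
        for node in sorted(out.nodes.values(), key=lambda n: (len(n.cells), n.id)):
            if node.id == ROOT or not out.siblings(node.id):
                continue
            reasons = _node_failures(out, node, counts, donors, batches, cfg)
            if reasons:
                failing.append((len(node.cells), node.id, reasons))
        if not failing:
            break
        merged_any = False
        for _, nid, reasons in failing:
            if nid not in out.nodes:
                continue  # merged away earlier in this pass
            sibs = out.siblings(nid)
            if not sibs:
                continue
            node = out.nodes[nid]
            dists = {
                s: float(np.linalg.norm(node.centroid - out.nodes[s].centroid))
                for s in sibs
            }
            target = min(sibs, key=lambda s: (dists[s], s))
            _merge_into(out, nid, target)
            merged_any = True
            out.prune_log.append(
                {
                    "iteration": iteration,
                    "node": nid,
                    "reasons": reasons,
                    "target": target,
                    "distances": dists,
                }
            )
        if not merged_any:
            break
    out.validate_nested()
    return out


def _merge_into(tree: ClusterTree, source_id: str, target_id: str) -> None:
    src = tree.nodes[source_id]
    tgt = tree.nodes[target_id]
    n_s, n_t = len(src.cells), len(tgt.cells)
    if src.centroid is not None and tgt.centroid is not None:
        tgt.centroid = (src.centroid * n_s + tgt.centroid * n_t) / (n_s + n_t)
    tgt.cells = np.sort(np.concatenate([tgt.cells, src.cells]))
    for child in src.children:
        tree.nodes[child].parent = target_id
        tgt.children.append(child)
    parent = tree.nodes[src.parent]
    parent.children.remove(source_id)
    del tree.nodes[source_id]


# ---------------------------------------------------------------------------
# expression-percentile cluster selection
# ---------------------------------------------------------------------------


def select_clusters_by_expression(
    counts: CountMatrix, labels, gene: str, percentile: float
) -> list:
    """Clusters in the upper expression-percentage percentile for a gene.

    Computes, per cluster, the fraction of cells with a nonzero count for
    ``gene`` and returns the clusters whose fraction reaches the given
    percentile (linear interpolation) of the per-cluster fraction
    distribution.  A gene expressed in no cell yields the empty set.
    """
    require(0 <= percentile <= 100, "percentile must be in [0, 100]")
    labels = np.asarray(labels)
    gi = counts.gene_index(gene)
    expressed = np.asarray((counts.matrix[:, gi] > 0).todense()).ravel()
    clusters = sorted(set(labels), key=str)
    fractions = np.array([expressed[labels == c].mean() for c in clusters])
    if fractions.max() == 0:
        return []
    cutoff = np.percentile(fractions, percentile)
    return [c for c, f in zip(clusters, fractions) if f >= cutoff]
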