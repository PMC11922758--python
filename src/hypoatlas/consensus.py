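"""Ensemble Leiden clustering and consensus partitions.

A k-nearest-neighbour graph is built once from the embedding, Leiden is run
many times with distinct seeds at a fixed resolution, and the runs are merged
into a single consensus partition with the hybrid bipartite graph formulation
(HBGF): cells and run-clusters form a bipartite graph that is partitioned by
spectral embedding followed by k-means on the cell vertices.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import igraph as ig
import leidenalg
import numpy as np
import scipy.sparse as sp
from scipy.sparse.linalg import svds
from sklearn.cluster import KMeans
from sklearn.neighbors import NearestNeighbors

from ._validate import ValidationError, require


@dataclass
class LabelEnsemble:
    """A stack of flat partitions of the same cells at one resolution."""

    resolution: float
    labels: np.ndarray  # cells x runs, integer labels
    seeds: list[int]

    @property
    def n_cells(self) -> int:
        return self.labels.shape[0]

    @property
    def n_runs(self) -> int:
        return self.labels.shape[1]


def build_knn_graph(embedding: np.ndarray, k_neighbors: int = 15) -> ig.Graph:
    """Undirected kNN graph (union of neighbour sets, Euclidean metric)."""
    embedding = np.asarray(embedding, dtype=float)
    n = embedding.shape[0]
    require(k_neighbors < n, "k_neighbors must be smaller than the number of cells")
    nn = NearestNeighbors(n_neighbors=k_neighbors + 1).fit(embedding)
    _, idx = nn.kneighbors(embedding)
    edges = {(min(i, j), max(i, j)) for i, row in enumerate(idx) for j in row[1:]}
    graph = ig.Graph(n=n, edges=sorted(edges), directed=False)
    return graph


def run_leiden_ensemble(
    embedding: np.ndarray,
    resolution: float,
    n_runs: int = 20,
    k_neighbors: int = 15,
    base_seed: int = 0,
) -> LabelEnsemble:
    """Run Leiden ``n_runs`` times on a shared kNN graph; run r uses seed base_seed + r."""
    require(n_runs >= 1, "n_runs must be >= 1")
    embedding = np.asarray(embedding, dtype=float)
    if np.allclose(embedding.std(axis=0), 0):
        warnings.warn("degenerate embedding (constant coordinates); clustering may be trivial")
    graph = build_knn_graph(embedding, k_neighbors)
    cols = []
    seeds = []
    for r in range(n_runs):
        seed = int(base_seed + r)
        part = leidenalg.find_partition(
            graph,
            leidenalg.RBConfigurationVertexPartition,
            resolution_parameter=resolution,
            seed=seed,
            n_iterations=2,
        )
        cols.append(np.asarray(part.membership, dtype=int))
        seeds.append(seed)
    return LabelEnsemble(resolution, np.column_stack(cols), seeds)


def _relabel_consecutive(labels: np.ndarray) -> np.ndarray:
    _, out = np.unique(labels, return_inverse=True)
    return out.astype(int)


def consensus_partition(ensemble, k: int | None = None, seed: int = 0) -> np.ndarray:
    """HBGF consensus of a label ensemble.

    Builds the bipartite cell/run-cluster incidence matrix, embeds it
    spectrally (top singular vectors of the degree-normalized incidence) and
    k-means-partitions the cell vertices.  ``k`` defaults to the median
    cluster count across runs.  A single-run ensemble is returned unchanged
    (relabeled to consecutive integers).
    """
    labels = ensemble.labels if isinstance(ensemble, LabelEnsemble) else np.asarray(ensemble)
    require(labels.ndim == 2 and labels.shape[1] >= 1, "ensemble must be cells x runs")
    n_cells, n_runs = labels.shape
    counts = [len(set(labels[:, r].tolist())) for r in range(n_runs)]
    if k is None:
        k = int(round(float(np.median(counts))))
    if k > n_cells:
        raise ValidationError(f"k={k} exceeds the number of cells ({n_cells})")
    if n_runs == 1:
        return _relabel_consecutive(labels[:, 0])
    if k <= 1:
        return np.zeros(n_cells, dtype=int)

    # incidence matrix: one column per (run, cluster)
    blocks = []
    for r in range(n_runs):
        col = _relabel_consecutive(labels[:, r])
        blocks.append(
            sp.csr_matrix(
                (np.ones(n_cells), (np.arange(n_cells), col)),
                shape=(n_cells, col.max() + 1),
            )
        )
    b = sp.hstack(blocks, format="csr")

    d1 = np.asarray(b.sum(axis=1)).ravel()  # = n_runs for every cell
    d2 = np.asarray(b.sum(axis=0)).ravel()  # run-cluster sizes
    d2 = np.where(d2 > 0, d2, 1.0)
    bn = sp.diags(1.0 / np.sqrt(d1)) @ b @ sp.diags(1.0 / np.sqrt(d2))

    n_comp = min(k, min(bn.shape) - 1)
    if n_comp < 1 or min(bn.shape) <= 4096:
        # dense LAPACK SVD: deterministic, and cheap at desk scale (the
        # second dimension is runs x clusters, typically a few hundred)
        u_full, _, _ = np.linalg.svd(bn.toarray(), full_matrices=False)
        u = u_full[:, : max(n_comp, 1)]
    else:
        v0 = np.full(min(bn.shape), 1.0 / np.sqrt(min(bn.shape)))
        u, _, _ = svds(bn, k=n_comp, v0=v0)
    norms = np.linalg.norm(u, axis=1, keepdims=True)
    u = u / np.where(norms > 0, norms, 1.0)
    km = KMeans(n_clusters=k, n_init=10, random_state=seed)
    part = km.fit_predict(u).astype(int)

    coassoc = coassociation_matrix(labels)
    candidates = [part]
    if n_cells <= 512:
        # small problems afford multi-start local search over the ensemble's
        # own columns as initializations
        seen = set()
        for r in range(n_runs):
            col = _relabel_consecutive(labels[:, r])
            key = tuple(col.tolist())
            if key in seen or col.max() + 1 > k:
                continue
            seen.add(key)
            candidates.append(col)
            if len(candidates) >= 9:
                break
    best_part, best_score = None, -np.inf
    for cand in candidates:
        refined = _refine_by_coassociation(cand, k, coassoc)
        score = coassociation_agreement(refined, coassoc)
        if score > best_score:
            best_part, best_score = refined, score
    return best_part


def _refine_by_coassociation(
    partition: np.ndarray, k: int, coassoc: np.ndarray, max_sweeps: int = 20
) -> np.ndarray:
    """Greedy single-cell moves maximizing co-association agreement.

    Polishes the spectral solution against the consensus objective itself:
    cell i prefers the block c maximizing sum_{j in c} (2 C_ij - 1), where C
    is the co-association matrix of the ensemble.
    """
    n = len(partition)
    m = 2.0 * coassoc - 1.0
    np.fill_diagonal(m, 0.0)
    part = partition.copy()
    onehot = np.zeros((n, k))
    onehot[np.arange(n), part] = 1.0
    for _ in range(max_sweeps):
        changed = False
        for i in range(n):  # sequential: each move strictly improves the objective
            scores = m[i] @ onehot
            best = int(scores.argmax())
            if scores[best] > scores[part[i]]:
                onehot[i, part[i]] = 0.0
                onehot[i, best] = 1.0
                part[i] = best
                changed = True
        if not changed:
            break
    return _relabel_consecutive(part)


# ---------------------------------------------------------------------------
# co-association utilities (objective used by the consensus oracle)
# ---------------------------------------------------------------------------


def coassociation_matrix(labels: np.ndarray) -> np.ndarray:
    """Fraction of runs in which each pair of cells is co-clustered."""
    labels = np.asarray(labels)
    n_cells, n_runs = labels.shape
    coassoc = np.zeros((n_cells, n_cells))
    for r in range(n_runs):
        col = labels[:, r]
        coassoc += (col[:, None] == col[None, :]).astype(float)
    return coassoc / n_runs


def coassociation_agreement(partition: np.ndarray, coassoc: np.ndarray) -> float:
    """Mean pairwise agreement between a partition and a co-association matrix.

    A co-clustered pair contributes its co-association frequency, a separated
    pair the complement; the score is averaged over all unordered pairs.
    """
    partition = np.asarray(partition)
    n = len(partition)
    same = partition[:, None] == partition[None, :]
    iu = np.triu_indices(n, k=1)
    agree = np.where(same[iu], coassoc[iu], 1.0 - coassoc[iu])
    return float(agree.mean())
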