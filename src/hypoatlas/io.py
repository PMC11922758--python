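"""Readers and writers for every format the pipeline touches.

Counts travel as MatrixMarket triplets with gene/barcode TSV sidecars (or as
dense CSV); tables as TSV; embeddings and abundance matrices as CSV; trees as
JSON (full payload) or Newick (topology and names only).  Internally
everything is 0-based; the 1-based MTX convention exists only at the file
boundary.
"""

from __future__ import annotations

import json
import warnings
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse as sp

from ._validate import ValidationError, require_columns
from .containers import CountMatrix
from .tree import ROOT, ClusterTree

# ---------------------------------------------------------------------------
# counts
# ---------------------------------------------------------------------------


def write_counts(counts: CountMatrix, path) -> None:
    """Write counts as ``matrix.mtx`` + ``genes.tsv`` + ``barcodes.tsv``.

    The MTX file is genes x cells (the common single-cell convention); the
    in-memory matrix is cells x genes, so it is transposed at the boundary.
    """
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    scipy.io.mmwrite(str(path / "matrix.mtx"), counts.matrix.T.tocoo())
    pd.Series(counts.genes).to_csv(path / "genes.tsv", sep="\t", index=False, header=False)
    pd.Series(counts.cells).to_csv(path / "barcodes.tsv", sep="\t", index=False, header=False)


def read_counts(path) -> CountMatrix:
    """Read counts from an MTX directory or a dense CSV (cells x genes)."""
    path = Path(path)
    if path.is_dir():
        mtx = path / "matrix.mtx"
        genes_f = path / "genes.tsv"
        cells_f = path / "barcodes.tsv"
        for f in (mtx, genes_f, cells_f):
            if not f.exists():
                raise ValidationError(f"missing counts file: {f}")
        matrix = sp.csr_matrix(scipy.io.mmread(str(mtx)).T)
        genes = pd.read_csv(genes_f, sep="\t", header=None)[0].to_numpy(dtype=object)
        cells = pd.read_csv(cells_f, sep="\t", header=None)[0].to_numpy(dtype=object)
        if matrix.shape != (len(cells), len(genes)):
            raise ValidationError(
                f"{mtx}: matrix is {matrix.shape[1]} genes x {matrix.shape[0]} cells but "
                f"sidecars list {len(genes)} genes and {len(cells)} cells"
            )
        if matrix.nnz == 0:
            warnings.warn(f"{mtx}: count matrix is empty")
        return CountMatrix(matrix, genes, cells)
    df = pd.read_csv(path, index_col=0)
    return CountMatrix(
        sp.csr_matrix(df.to_numpy()),
        df.columns.to_numpy(dtype=object),
        df.index.to_numpy(dtype=object),
    )


# ---------------------------------------------------------------------------
# tables
# ---------------------------------------------------------------------------


def read_cell_table(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    require_columns(df, ["cell_id"], f"cell table {path}")
    if df["cell_id"].duplicated().any():
        raise ValidationError(f"{path}: duplicate cell_id values")
    return df


def write_cell_table(cells: pd.DataFrame, path) -> None:
    cells.to_csv(path, sep="\t", index=False)


def read_labels(path) -> pd.DataFrame:
    """Label table: cell_id plus one column per clustering level."""
    df = pd.read_csv(path, sep="\t")
    require_columns(df, ["cell_id"], f"label table {path}")
    return df


def write_labels(labels: pd.DataFrame, path) -> None:
    labels.to_csv(path, sep="\t", index=False)


def read_embedding(path) -> pd.DataFrame:
    df = pd.read_csv(path, index_col=0)
    if not np.isfinite(df.to_numpy(dtype=float)).all():
        raise ValidationError(f"{path}: embedding contains non-finite values")
    return df


def write_embedding(embedding, cell_ids, path) -> None:
    pd.DataFrame(np.asarray(embedding), index=cell_ids).to_csv(path)


def read_homology(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    require_columns(df, ["gene_a", "gene_b", "similarity"], f"homology table {path}")
    return df


def read_abundance(path) -> pd.DataFrame:
    df = pd.read_csv(path, index_col=0)
    if (df.to_numpy(dtype=float) < 0).any():
        raise ValidationError(f"{path}: abundance matrix has negative entries")
    return df


def write_abundance(abundance: pd.DataFrame, path) -> None:
    abundance.to_csv(path)


def read_specificity(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col=0)


def write_specificity(spec: pd.DataFrame, path) -> None:
    spec.to_csv(path, sep="\t")


def read_ranks(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    require_columns(df, ["gene", "rank"], f"rank table {path}")
    df = df.set_index("gene")
    ranks = np.sort(df["rank"].to_numpy())
    if not np.array_equal(ranks, np.arange(1, len(df) + 1)):
        raise ValidationError(f"{path}: ranks are not a permutation of 1..n")
    return df


def write_ranks(ranks: pd.DataFrame, path) -> None:
    ranks.reset_index().to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# trees
# ---------------------------------------------------------------------------

_NEWICK_SPECIAL = set("()[]{}:;,'\" \t\n")


def _newick_name(name: str) -> str:
    if any(ch in _NEWICK_SPECIAL for ch in name):
        return "'" + name.replace("'", "''") + "'"
    return name


def _newick_subtree(tree: ClusterTree, node_id: str) -> str:
    node = tree.nodes[node_id]
    name = _newick_name(node.id)
    if not node.children:
        return name
    inner = ",".join(_newick_subtree(tree, c) for c in sorted(node.children))
    return f"({inner}){name}"


def export_tree(tree: ClusterTree, path, format: str = "json") -> None:
    """Serialize a cluster tree as JSON (full payload) or Newick (topology)."""
    path = Path(path)
    if format == "json":
        path.write_text(json.dumps(tree.to_dict(), indent=1))
    elif format == "newick":
        path.write_text(_newick_subtree(tree, ROOT) + ";\n")
    else:
        raise ValidationError(f"unknown tree format {format!r}")


def import_tree(path) -> ClusterTree:
    payload = json.loads(Path(path).read_text())
    tree = ClusterTree.from_dict(payload)
    tree.validate_nested()
    return tree
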