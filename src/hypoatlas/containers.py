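"""In-memory containers shared across the pipeline."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp

from ._validate import ValidationError


@dataclass
class CountMatrix:
    """Sparse gene-expression count matrix, cells x genes.

    The matrix is stored cells-by-genes (CSR) so that per-cell slicing is
    cheap; the MTX file boundary (genes-by-cells, 1-based) is handled by the
    readers/writers in :mod:`hypoatlas.io`.
    """

    matrix: sp.csr_matrix
    genes: np.ndarray
    cells: np.ndarray

    def __post_init__(self) -> None:
        self.matrix = sp.csr_matrix(self.matrix)
        self.genes = np.asarray(self.genes, dtype=object)
        self.cells = np.asarray(self.cells, dtype=object)
        n_cells, n_genes = self.matrix.shape
        if len(self.genes) != n_genes:
            raise ValidationError(
                f"gene sidecar length {len(self.genes)} != matrix gene dimension {n_genes}"
            )
        if len(self.cells) != n_cells:
            raise ValidationError(
                f"cell sidecar length {len(self.cells)} != matrix cell dimension {n_cells}"
            )
        if len(set(self.genes)) != n_genes:
            raise ValidationError("gene ids are not unique")
        if len(set(self.cells)) != n_cells:
            raise ValidationError("cell ids are not unique")

    @property
    def n_cells(self) -> int:
        return self.matrix.shape[0]

    @property
    def n_genes(self) -> int:
        return self.matrix.shape[1]

    def gene_index(self, gene: str) -> int:
        idx = np.flatnonzero(self.genes == gene)
        if idx.size == 0:
            raise ValidationError(f"gene {gene!r} not present in count matrix")
        return int(idx[0])

    def subset_cells(self, rows) -> "CountMatrix":
        rows = np.asarray(rows)
        return CountMatrix(self.matrix[rows], self.genes, self.cells[rows])

    def subset_genes(self, cols) -> "CountMatrix":
        cols = np.asarray(cols)
        return CountMatrix(self.matrix[:, cols], self.genes[cols], self.cells)

    def detection_fraction(self) -> np.ndarray:
        """Per-gene fraction of cells with a nonzero count."""
        return np.asarray((self.matrix > 0).mean(axis=0)).ravel()

    def dense(self) -> np.ndarray:
        return self.matrix.toarray()
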