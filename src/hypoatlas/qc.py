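"""Nucleus- and cluster-level quality control.

Nuclei are kept when they have at least ``min_umi`` UMIs, at most ``max_mito``
mitochondrial fraction and are not flagged as doublets (boundary values are
inclusive).  Separately, whole clusters whose doublet fraction exceeds
``doublet_cluster_fraction`` (strictly) are removed, doublet and non-doublet
members alike.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from ._validate import ValidationError, require, require_columns

REQUIRED_CELL_COLUMNS = ["cell_id", "umi_count", "mito_fraction", "doublet_flag"]


@dataclass(frozen=True)
class QCConfig:
    min_umi: int = 800
    max_mito: float = 0.10
    doublet_cluster_fraction: float = 0.75

    def __post_init__(self) -> None:
        require(self.min_umi >= 0, "min_umi must be nonnegative")
        require(0 < self.max_mito <= 1, "max_mito must be in (0, 1]")
        require(
            0 < self.doublet_cluster_fraction <= 1,
            "doublet_cluster_fraction must be in (0, 1]",
        )


def filter_nuclei(cells: pd.DataFrame, cfg: QCConfig | None = None):
    """Split a cell table into kept and removed nuclei.

    Returns ``(kept, removed, summary)``; kept and removed are disjoint and
    together equal the input.  ``summary`` counts each failure mode (a nucleus
    can fail several).
    """
    cfg = cfg or QCConfig()
    require_columns(cells, REQUIRED_CELL_COLUMNS, "cell table")
    umi_ok = cells["umi_count"] >= cfg.min_umi
    mito_ok = cells["mito_fraction"] <= cfg.max_mito
    singlet = ~cells["doublet_flag"].astype(bool)
    keep = umi_ok & mito_ok & singlet
    summary = {
        "n_input": int(len(cells)),
        "n_kept": int(keep.sum()),
        "n_removed": int((~keep).sum()),
        "n_low_umi": int((~umi_ok).sum()),
        "n_high_mito": int((~mito_ok).sum()),
        "n_doublet": int((~singlet).sum()),
    }
    return cells[keep].copy(), cells[~keep].copy(), summary


def drop_doublet_clusters(
    cells: pd.DataFrame, level: str, cfg: QCConfig | None = None
) -> pd.DataFrame:
    """Remove every cell of clusters dominated by doublets.

    A cluster is dropped when strictly more than ``doublet_cluster_fraction``
    of its members are flagged doublets.
    """
    cfg = cfg or QCConfig()
    require_columns(cells, ["doublet_flag", level], "cell table")
    if cells[level].isna().any():
        raise ValidationError(f"cells without a {level!r} label cannot be cluster-filtered")
    frac = cells.groupby(level)["doublet_flag"].mean()
    bad = set(frac[frac > cfg.doublet_cluster_fraction].index)
    return cells[~cells[level].isin(bad)].copy()
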