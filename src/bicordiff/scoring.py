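"""Per-gene differential coexpression (dc) scores.

For gene i with informative neighbours j_1..j_n, let X = (C1(i, j_k)) and
Y = (C2(i, j_k)) be its correlations to those neighbours in the two
conditions, gathered in the same neighbour order.  The dc score is the
root-mean-square coexpression change

    dc_i = sqrt( sum_k (X_k - Y_k)^2 / n ),

bounded in [0, 2] since correlations lie in [-1, 1].  Genes are ranked by
descending dc; a gene with no informative neighbours carries no evidence, so
its dc is missing (not 0) and it is ranked after all scored genes.
"""

from __future__ import annotations

import math

import numpy as np
import pandas as pd


def dc_value(x, y) -> float:
    """Root-mean-square difference between two aligned correlation vectors."""
    xv = np.asarray(x, dtype=float)
    yv = np.asarray(y, dtype=float)
    if xv.shape != yv.shape or xv.ndim != 1:
        raise ValueError("x and y must be 1-D vectors of equal length")
    if xv.size == 0:
        raise ValueError("dc undefined for zero informative neighbours")
    return float(math.sqrt(np.mean((xv - yv) ** 2)))


def _dc_from_arrays(C1: np.ndarray, C2: np.ndarray, kept: np.ndarray):
    """Vectorised dc over all genes: returns (dc, n_neighbors) arrays."""
    n = kept.sum(axis=1)
    diff2 = np.where(kept, (C1 - C2) ** 2, 0.0)
    with np.errstate(invalid="ignore", divide="ignore"):
        dc = np.sqrt(diff2.sum(axis=1) / n)
    dc[n == 0] = np.nan
    return dc, n.astype(int)


def dc_table(C1: pd.DataFrame, C2: pd.DataFrame, mask: pd.DataFrame) -> pd.DataFrame:
    """dc score, neighbour count and rank for every gene.

    All three inputs must share gene ids and ordering.  Neighbour correlations
    are gathered in ascending input gene order in both conditions, so the
    vectors are aligned pair by pair.
    """
    if not (C1.index.equals(C2.index) and C1.index.equals(mask.index)):
        raise ValueError("C1, C2 and mask must share gene ids and ordering")
    dc, n = _dc_from_arrays(
        np.asarray(C1, dtype=float),
        np.asarray(C2, dtype=float),
        np.asarray(mask, dtype=bool),
    )
    table = pd.DataFrame({"dc": dc, "n_neighbors": n}, index=C1.index)
    table.index.name = "gene_id"
    return rank_genes(table)


def rank_genes(table: pd.DataFrame) -> pd.DataFrame:
    """Assign ranks 1..G by descending dc; stable tie-break on input order.

    Missing dc values rank after every finite one, preserving input order
    among themselves.
    """
    dc = np.asarray(table["dc"], dtype=float)
    order = sorted(
        range(len(dc)),
        key=lambda i: (np.isnan(dc[i]), -dc[i] if not np.isnan(dc[i]) else 0.0, i),
    )
    ranks = np.empty(len(dc), dtype=int)
    ranks[order] = np.arange(1, len(dc) + 1)
    out = table.copy()
    out["rank"] = ranks
    return out
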