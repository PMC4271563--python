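"""Half-thresholding: keep a gene pair if either condition's correlation passes.

Hard-thresholding discards the continuous correlation values; soft-thresholding
keeps every noisy pair.  The half-thresholding compromise retains a pair's
correlation values *in both conditions* whenever at least one condition's
correlation magnitude exceeds the threshold, and discards "non-informative"
pairs that fail in both.  The surviving mask defines each gene's informative
neighbours for downstream differential-coexpression scoring.
"""

from __future__ import annotations

import numpy as np
import pandas as pd


def _check_aligned(C1: pd.DataFrame, C2: pd.DataFrame) -> None:
    if not C1.index.equals(C2.index) or not C1.columns.equals(C2.columns):
        raise ValueError("correlation matrices must share gene ids and ordering")


def half_threshold_mask(
    C1: pd.DataFrame,
    C2: pd.DataFrame,
    tau: float,
    absolute: bool = True,
) -> pd.DataFrame:
    """Boolean mask of informative gene pairs.

    A pair (i, j), i != j, is kept when |C1(i,j)| > tau OR |C2(i,j)| > tau
    (strictly greater).  Missing correlations count as below threshold, and a
    pair with a missing value in either condition is dropped entirely — there
    is no coexpression change to measure for it.

    Parameters
    ----------
    C1, C2 : DataFrame
        Condition-specific correlation matrices with identical gene order.
    tau : float in [0, 1]
        Half-threshold.
    absolute : bool
        Compare |correlation| (default, so strong negative coexpression is
        informative) or the signed value.
    """
    _check_aligned(C1, C2)
    if not 0.0 <= tau <= 1.0:
        raise ValueError(f"tau must be in [0, 1], got {tau}")
    V1 = np.asarray(C1, dtype=float)
    V2 = np.asarray(C2, dtype=float)
    if absolute:
        V1, V2 = np.abs(V1), np.abs(V2)
    finite = np.isfinite(V1) & np.isfinite(V2)
    with np.errstate(invalid="ignore"):
        kept = ((V1 > tau) | (V2 > tau)) & finite
    np.fill_diagonal(kept, False)
    return pd.DataFrame(kept, index=C1.index, columns=C1.columns)


def informative_neighbors(mask: pd.DataFrame, gene) -> list:
    """Informative neighbours of ``gene``, in input gene order."""
    if gene not in mask.index:
        raise KeyError(f"unknown gene {gene!r}")
    row = mask.loc[gene]
    return [g for g in mask.index if g != gene and bool(row[g])]


def mask_edge_list(
    mask: pd.DataFrame,
    C1: pd.DataFrame,
    C2: pd.DataFrame,
    tau: float,
    absolute: bool = True,
) -> pd.DataFrame:
    """Audit table of kept pairs: gene_i, gene_j, which condition(s) passed tau."""
    _check_aligned(C1, C2)
    genes = list(mask.index)
    rows = []
    kept = np.asarray(mask, dtype=bool)
    V1 = np.asarray(C1, dtype=float)
    V2 = np.asarray(C2, dtype=float)
    A1 = np.abs(V1) if absolute else V1
    A2 = np.abs(V2) if absolute else V2
    for i in range(len(genes)):
        for j in range(i + 1, len(genes)):
            if not kept[i, j]:
                continue
            p1, p2 = A1[i, j] > tau, A2[i, j] > tau
            reason = "both" if (p1 and p2) else ("condition1" if p1 else "condition2")
            rows.append((genes[i], genes[j], V1[i, j], V2[i, j], reason))
    return pd.DataFrame(
        rows, columns=["gene_i", "gene_j", "corr_condition1", "corr_condition2", "kept_by"]
    )
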