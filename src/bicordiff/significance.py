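"""Permutation significance for dc scores and Benjamini-Hochberg FDR.

Under the null hypothesis all genes are mutually independent in both
conditions, so the condition labels are exchangeable.  The test pools the
samples of the two conditions, reassigns them at random into groups of the
original sizes M times, and re-runs the whole scoring pipeline — bicor
matrices, half-threshold mask, dc — on each relabelled pair.  The p-value of
gene i is the fraction of permutations whose recomputed dc_i is at least the
observed one, so p-values live on the grid {0, 1/M, ..., 1}.  Benjamini-
Hochberg converts them to q-values (estimated FDR).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .bicor import BicorOptions, bicor_matrix
from .filtering import half_threshold_mask
from .scoring import _dc_from_arrays, dc_table


@dataclass(frozen=True)
class PermutationConfig:
    """Permutation-test settings.

    m_permutations : number of random relabellings M (p-value resolution 1/M).
    seed : RNG seed for reproducible relabellings.
    preserve_group_sizes : keep the original group sizes in every permutation
        (the standard two-group label permutation); if False, each sample is
        assigned to a group uniformly at random, redrawing until both groups
        have at least 2 samples.
    plus_one : use the (count + 1) / (M + 1) p-value estimator instead of the
        raw fraction, so p = 0 is unattainable and BH stays interpretable.
    """

    m_permutations: int = 1000
    seed: int | None = None
    preserve_group_sizes: bool = True
    plus_one: bool = False

    def __post_init__(self) -> None:
        if self.m_permutations < 1:
            raise ValueError("m_permutations must be >= 1")


def permute_condition_labels(
    E1: pd.DataFrame, E2: pd.DataFrame, rng: np.random.Generator,
    preserve_group_sizes: bool = True,
):
    """Randomly reassign pooled samples to two groups of the original sizes.

    Gene rows are untouched; only the condition labels move.  Returns two
    DataFrames with the same gene index as the inputs.
    """
    if not E1.index.equals(E2.index):
        raise ValueError("both conditions must share gene ids and ordering")
    n1, n2 = E1.shape[1], E2.shape[1]
    if n1 < 2 or n2 < 2:
        raise ValueError("need at least 2 samples per group")
    pooled = np.hstack([np.asarray(E1, float), np.asarray(E2, float)])
    labels = list(E1.columns) + list(E2.columns)
    if preserve_group_sizes:
        perm = rng.permutation(n1 + n2)
    else:
        while True:
            assign = rng.integers(0, 2, size=n1 + n2)
            if 2 <= assign.sum() <= n1 + n2 - 2:
                break
        perm = np.concatenate([np.flatnonzero(assign == 0), np.flatnonzero(assign == 1)])
        n1 = int((assign == 0).sum())
    idx1, idx2 = perm[:n1], perm[n1:]
    P1 = pd.DataFrame(pooled[:, idx1], index=E1.index, columns=[labels[i] for i in idx1])
    P2 = pd.DataFrame(pooled[:, idx2], index=E1.index, columns=[labels[i] for i in idx2])
    return P1, P2


def _dc_scores(E1, E2, tau, opts, absolute=True):
    C1 = bicor_matrix(E1, opts)
    C2 = bicor_matrix(E2, opts)
    kept = half_threshold_mask(C1, C2, tau, absolute=absolute)
    dc, n = _dc_from_arrays(
        np.asarray(C1, float), np.asarray(C2, float), np.asarray(kept, bool)
    )
    return dc, n, C1, C2, kept


def permutation_pvalues(
    E1: pd.DataFrame,
    E2: pd.DataFrame,
    tau: float,
    opts: BicorOptions | None = None,
    cfg: PermutationConfig | None = None,
    absolute: bool = True,
) -> pd.DataFrame:
    """Observed dc table with permutation p-values and BH q-values.

    Every permutation recomputes the bicor matrices and the half-threshold
    mask on the relabelled data, then the dc scores, and the exceedance count
    uses >= (a permuted dc equal to the observed one counts against the gene).
    A permuted dc that is undefined (no informative neighbours in that
    permutation) never exceeds.  Genes with undefined observed dc get missing
    p and q.
    """
    opts = opts or BicorOptions()
    cfg = cfg or PermutationConfig()
    rng = np.random.default_rng(cfg.seed)

    dc_obs, n_obs, C1, C2, kept = _dc_scores(E1, E2, tau, opts, absolute)
    exceed = np.zeros(len(dc_obs))
    for _ in range(cfg.m_permutations):
        P1, P2 = permute_condition_labels(
            E1, E2, rng, preserve_group_sizes=cfg.preserve_group_sizes
        )
        dc_m, _, _, _, _ = _dc_scores(P1, P2, tau, opts, absolute)
        with np.errstate(invalid="ignore"):
            exceed += np.nan_to_num(dc_m, nan=-np.inf) >= dc_obs

    if cfg.plus_one:
        p = (exceed + 1.0) / (cfg.m_permutations + 1.0)
    else:
        p = exceed / cfg.m_permutations
    p[np.isnan(dc_obs)] = np.nan

    table = dc_table(
        pd.DataFrame(np.asarray(C1), index=E1.index, columns=E1.index),
        pd.DataFrame(np.asarray(C2), index=E1.index, columns=E1.index),
        kept,
    )
    table["p_value"] = p
    table["q_value"] = bh_qvalues(p)
    return table[["dc", "n_neighbors", "rank", "p_value", "q_value"]]


def bh_qvalues(p) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values; missing p-values pass through.

    q_(k) = min_{j >= k} ( p_(j) * n / j ), capped at 1, mapped back to the
    input order.
    """
    p = np.asarray(p, dtype=float)
    finite = ~np.isnan(p)
    if np.any((p[finite] < 0) | (p[finite] > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    q = np.full(p.shape, np.nan)
    if finite.any():
        q[finite] = np.minimum(stats.false_discovery_control(p[finite], method="bh"), 1.0)
    return q
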