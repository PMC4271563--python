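"""Model/Results interface for differential coexpression analysis.

``DifferentialCoexpression`` holds the two condition matrices and the network
parameters; ``fit`` runs the permutation test and returns a
``DifferentialCoexpressionResults`` carrying the per-gene scores, their
permutation p-values and BH q-values, a ``summary()`` table, and the
clique-module analysis of the fitted correlation structure.

Example
-------
>>> from bicordiff import DifferentialCoexpression, SimulationSpec
>>> from bicordiff.simulate import generate_condition_pair
>>> e1, e2 = generate_condition_pair(SimulationSpec(seed=7))
>>> res = DifferentialCoexpression(e1.data, e2.data, tau=0.4).fit(
...     m_permutations=200, seed=7)
>>> res.table.head()          # doctest: +SKIP
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .bicor import BicorOptions, PEARSON_FALLBACK, bicor_matrix
from .cliques import (
    drop_isolated_nodes,
    dual_threshold_adjacency,
    enumerate_cliques,
    merge_cliques,
    threshold_grid,
)
from .filtering import half_threshold_mask
from .io import ExpressionMatrix, read_expression, select_genes
from .significance import PermutationConfig, permutation_pvalues


class DifferentialCoexpression:
    """Differential coexpression model for a two-condition expression pair.

    Parameters
    ----------
    condition1, condition2 : DataFrame
        Genes x samples expression tables sharing the same gene set (rows are
        reordered to condition 1's order).  Typically normal vs disease.
    tau : float
        Half-threshold on |bicor| defining informative gene pairs.
    max_p_outliers : float
        Per-side cap on the proportion of zero-weight outliers in bicor
        (1 disables capping).
    zero_mad_policy : str
        Handling of constant-ish genes, see :class:`bicordiff.BicorOptions`.
    absolute : bool
        Threshold |correlation| (default) rather than the signed value.
    """

    def __init__(
        self,
        condition1: pd.DataFrame,
        condition2: pd.DataFrame,
        tau: float = 0.4,
        max_p_outliers: float = 1.0,
        zero_mad_policy: str = PEARSON_FALLBACK,
        absolute: bool = True,
    ) -> None:
        if isinstance(condition1, ExpressionMatrix):
            condition1 = condition1.data
        if isinstance(condition2, ExpressionMatrix):
            condition2 = condition2.data
        if set(condition1.index) != set(condition2.index):
            diff = sorted(set(condition1.index) ^ set(condition2.index), key=str)
            raise ValueError(f"gene sets differ; first 10 mismatched: {diff[:10]}")
        self.condition1 = condition1
        self.condition2 = condition2.loc[condition1.index]
        if not 0.0 <= tau <= 1.0:
            raise ValueError(f"tau must be in [0, 1], got {tau}")
        self.tau = tau
        self.absolute = absolute
        self.options = BicorOptions(
            max_p_outliers=max_p_outliers, zero_mad_policy=zero_mad_policy
        )

    @classmethod
    def from_files(cls, path1, path2, **kwargs) -> "DifferentialCoexpression":
        """Build the model from two delimited-text expression files."""
        read_kwargs = {
            k: kwargs.pop(k)
            for k in ("delimiter", "transpose", "impute_median")
            if k in kwargs
        }
        e1 = read_expression(path1, **read_kwargs)
        e2 = read_expression(path2, **read_kwargs)
        return cls(e1.data, e2.data, **kwargs)

    def correlations(self):
        """The two fitted bicor matrices (computed on demand)."""
        return (
            bicor_matrix(self.condition1, self.options),
            bicor_matrix(self.condition2, self.options),
        )

    def fit(
        self,
        m_permutations: int = 1000,
        seed: int | None = None,
        plus_one: bool = False,
    ) -> "DifferentialCoexpressionResults":
        """Run the permutation test and return the results object."""
        cfg = PermutationConfig(
            m_permutations=m_permutations, seed=seed, plus_one=plus_one
        )
        table = permutation_pvalues(
            self.condition1,
            self.condition2,
            self.tau,
            opts=self.options,
            cfg=cfg,
            absolute=self.absolute,
        )
        return DifferentialCoexpressionResults(self, table, cfg)


class DifferentialCoexpressionResults:
    """Fitted differential-coexpression results.

    Attributes
    ----------
    table : DataFrame
        Per gene: dc score, informative-neighbour count, rank, permutation
        p-value and BH q-value (missing for genes without informative pairs).
    model : DifferentialCoexpression
    """

    def __init__(self, model, table: pd.DataFrame, cfg: PermutationConfig) -> None:
        self.model = model
        self.table = table
        self.permutation_config = cfg
        self._corr = None

    @property
    def correlations(self):
        if self._corr is None:
            self._corr = self.model.correlations()
        return self._corr

    @property
    def informative_mask(self) -> pd.DataFrame:
        C1, C2 = self.correlations
        return half_threshold_mask(C1, C2, self.model.tau, absolute=self.model.absolute)

    def top_genes(
        self, top_fraction: float | None = None, p_cutoff: float | None = None
    ) -> list:
        """Selected differential-coexpression genes (see io.select_genes)."""
        return select_genes(self.table, top_fraction=top_fraction, p_cutoff=p_cutoff)

    def module(self, t1: float = 0.76, t2: float = 0.2, min_clique_size: int = 4,
               maximal: bool = True):
        """Dual-threshold clique module of the fitted correlation structure.

        Edges require |corr| >= t1 in condition 1 and <= t2 in condition 2
        (coexpression lost in condition 2).  Returns ``(cliques, module)``.
        """
        C1, C2 = self.correlations
        adj = drop_isolated_nodes(dual_threshold_adjacency(C1, C2, t1, t2))
        cliques = (
            enumerate_cliques(adj, min_size=min_clique_size, maximal=maximal)
            if not adj.empty
            else []
        )
        return cliques, merge_cliques(cliques, adj)

    def threshold_scan(self, t1_values=None, t2_values=None) -> pd.DataFrame:
        """Isolated-node proportion and graph density across a threshold grid."""
        grid = np.round(np.linspace(0.1, 0.9, 9), 2)
        C1, C2 = self.correlations
        return threshold_grid(
            C1, C2, t1_values if t1_values is not None else grid,
            t2_values if t2_values is not None else grid,
        )

    def summary(self, top: int = 10) -> str:
        """Human-readable fit summary: parameters and the top-ranked genes."""
        t = self.table.sort_values("rank")
        n_scored = int(t["dc"].notna().sum())
        lines = [
            "Differential coexpression (biweight midcorrelation, half-threshold)",
            "=" * 68,
            f"genes: {len(t)}    scored (>=1 informative neighbour): {n_scored}",
            f"samples: {self.model.condition1.shape[1]} + {self.model.condition2.shape[1]}",
            f"tau: {self.model.tau}    permutations: {self.permutation_config.m_permutations}"
            f"    seed: {self.permutation_config.seed}",
            f"p-value resolution: {1.0 / self.permutation_config.m_permutations:g}",
            "-" * 68,
            t.head(top).to_string(
                float_format=lambda v: f"{v:.4f}", na_rep="."
            ),
        ]
        return "\n".join(lines)

    def to_tsv(self, path) -> None:
        self.table.to_csv(path, sep="\t")
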