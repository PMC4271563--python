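"""File formats, run configuration and the end-to-end pipeline entry points.

Expression matrices travel as delimited text: first column gene identifiers,
header row of sample identifiers, genes as rows (a ``transpose`` flag covers
samples-as-rows files).  Outputs are plain TSV tables plus a key:value run
log so every run is reconstructible from its artifacts.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .bicor import BicorOptions, PEARSON_FALLBACK, bicor_matrix, robust_mad
from .cliques import (
    drop_isolated_nodes,
    dual_threshold_adjacency,
    enumerate_cliques,
    merge_cliques,
    threshold_grid,
)
from .significance import PermutationConfig, permutation_pvalues

logger = logging.getLogger(__name__)


@dataclass
class ExpressionMatrix:
    """A genes x samples expression table for one condition."""

    data: pd.DataFrame
    condition: str = ""

    def __post_init__(self) -> None:
        if self.data.index.has_duplicates:
            dupes = self.data.index[self.data.index.duplicated()].unique().tolist()
            raise ValueError(f"duplicate gene identifiers: {dupes[:10]}")
        if self.data.columns.has_duplicates:
            dupes = self.data.columns[self.data.columns.duplicated()].unique().tolist()
            raise ValueError(f"duplicate sample identifiers: {dupes[:10]}")

    @property
    def gene_ids(self) -> list:
        return list(self.data.index)

    @property
    def sample_ids(self) -> list:
        return list(self.data.columns)


@dataclass
class RunConfig:
    """Pipeline defaults.

    tau : half-threshold on |bicor| for informative pairs.
    m_permutations : permutation count M (p-value resolution 1/M).
    t1, t2 : dual-condition adjacency thresholds (strong in condition 1,
        lost in condition 2).
    min_clique_size : smallest clique reported.
    max_p_outliers : per-side outlier-proportion cap for bicor (1 = off).
    top_fraction / p_cutoff : the two supported gene-selection rules.
    """

    tau: float = 0.4
    m_permutations: int = 1000
    seed: int = 0
    t1: float = 0.76
    t2: float = 0.2
    min_clique_size: int = 4
    max_p_outliers: float = 1.0
    top_fraction: float = 0.07
    p_cutoff: float = 0.05
    zero_mad_policy: str = PEARSON_FALLBACK
    absolute: bool = True
    plus_one: bool = False

    def __post_init__(self) -> None:
        for name in ("tau", "t1", "t2", "top_fraction", "p_cutoff"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if self.m_permutations < 1:
            raise ValueError("m_permutations must be >= 1")
        if self.min_clique_size < 2:
            raise ValueError("min_clique_size must be >= 2")

    def bicor_options(self) -> BicorOptions:
        return BicorOptions(
            max_p_outliers=self.max_p_outliers, zero_mad_policy=self.zero_mad_policy
        )


def _sniff_delimiter(path: Path) -> str:
    with open(path) as handle:
        first = handle.readline()
    return "\t" if "\t" in first else ","


def read_expression(
    path,
    delimiter: str | None = None,
    transpose: bool = False,
    impute_median: bool = False,
    condition: str = "",
) -> ExpressionMatrix:
    """Load an expression matrix from delimited text.

    The delimiter is auto-detected among tab/comma unless forced.  Duplicate
    gene ids, non-numeric cells and (by default) missing values are rejected
    with messages naming the offending id or cell; ``impute_median``
    substitutes per-gene medians for missing cells instead, logging the count.
    """
    path = Path(path)
    sep = delimiter or _sniff_delimiter(path)
    raw = pd.read_csv(path, sep=sep, index_col=0)
    if transpose:
        raw = raw.T
    for col in raw.columns:
        converted = pd.to_numeric(raw[col], errors="coerce")
        bad = converted.isna() & raw[col].notna()
        if bad.any():
            gene = raw.index[bad.to_numpy().nonzero()[0][0]]
            raise ValueError(
                f"non-numeric cell at gene {gene!r}, sample {col!r} in {path.name}"
            )
        raw[col] = converted
    if raw.isna().to_numpy().any():
        if impute_median:
            n_missing = int(raw.isna().to_numpy().sum())
            raw = raw.apply(lambda row: row.fillna(row.median()), axis=1)
            logger.info("imputed %d missing cells with per-gene medians", n_missing)
        else:
            gene = raw.index[raw.isna().any(axis=1)][0]
            raise ValueError(
                f"missing value(s), first at gene {gene!r}; "
                "pass impute_median=True to fill with per-gene medians"
            )
    return ExpressionMatrix(raw.astype(float), condition=condition or path.stem)


def write_expression(em: ExpressionMatrix, path, sep: str = "\t") -> None:
    em.data.to_csv(path, sep=sep, index_label="gene_id")


def _check_gene_sets(E1: ExpressionMatrix, E2: ExpressionMatrix) -> pd.DataFrame:
    """Align condition 2 to condition 1's gene order; error on set mismatch."""
    s1, s2 = set(E1.gene_ids), set(E2.gene_ids)
    if s1 != s2:
        diff = sorted(s1 ^ s2, key=str)
        raise ValueError(
            f"gene sets differ between conditions; {len(diff)} mismatched, "
            f"first 10: {diff[:10]}"
        )
    return E2.data.loc[E1.data.index]


def _zero_mad_genes(data: pd.DataFrame) -> list:
    return [g for g in data.index if robust_mad(data.loc[g].to_numpy()) == 0.0]


def run_pipeline(
    config: RunConfig,
    normal: ExpressionMatrix | str | Path,
    disease: ExpressionMatrix | str | Path,
    out_dir: str | Path | None = None,
    write_correlations: bool = False,
) -> pd.DataFrame:
    """Full differential-coexpression run: bicor x2, half-threshold, dc,
    permutation p-values, BH q-values.

    Accepts loaded matrices or file paths.  When ``out_dir`` is given, writes
    ``dc_table.tsv``, a ``run.log`` (parameters, seed, zero-MAD genes,
    p-value resolution) and optionally the two correlation matrices.
    """
    E1 = normal if isinstance(normal, ExpressionMatrix) else read_expression(normal)
    E2 = disease if isinstance(disease, ExpressionMatrix) else read_expression(disease)
    d2 = _check_gene_sets(E1, E2)

    opts = config.bicor_options()
    cfg = PermutationConfig(
        m_permutations=config.m_permutations,
        seed=config.seed,
        plus_one=config.plus_one,
    )
    table = permutation_pvalues(
        E1.data, d2, config.tau, opts=opts, cfg=cfg, absolute=config.absolute
    )

    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        table.to_csv(out_dir / "dc_table.tsv", sep="\t")
        log = dict(asdict(config))
        log["zero_mad_genes_condition1"] = _zero_mad_genes(E1.data)
        log["zero_mad_genes_condition2"] = _zero_mad_genes(d2)
        log["p_value_resolution"] = 1.0 / config.m_permutations
        log["n_genes"] = len(E1.gene_ids)
        log["n_samples"] = [len(E1.sample_ids), E2.data.shape[1]]
        (out_dir / "run.log").write_text(yaml.safe_dump(log, sort_keys=False))
        if write_correlations:
            bicor_matrix(E1.data, opts).to_csv(out_dir / "bicor_condition1.tsv", sep="\t")
            bicor_matrix(d2, opts).to_csv(out_dir / "bicor_condition2.tsv", sep="\t")
    return table


def run_cliques(
    config: RunConfig,
    normal: ExpressionMatrix | str | Path,
    disease: ExpressionMatrix | str | Path,
    gene_subset: list | str | Path | None = None,
    out_dir: str | Path | None = None,
    all_cliques: bool = False,
    graphml: bool = False,
):
    """Dual-threshold adjacency, clique mining and module merge.

    ``gene_subset`` (a list or a one-id-per-line file) restricts the analysis
    to a candidate gene set before correlation; ids absent from the data are
    an error.  Returns ``(cliques, module, diagnostic)``.
    """
    E1 = normal if isinstance(normal, ExpressionMatrix) else read_expression(normal)
    E2 = disease if isinstance(disease, ExpressionMatrix) else read_expression(disease)
    d2 = _check_gene_sets(E1, E2)
    d1 = E1.data

    if gene_subset is not None:
        if not isinstance(gene_subset, (list, tuple)):
            gene_subset = [
                line.strip()
                for line in Path(gene_subset).read_text().splitlines()
                if line.strip()
            ]
        missing = [g for g in gene_subset if g not in d1.index]
        if missing:
            raise ValueError(f"subset ids absent from data: {missing[:10]}")
        d1 = d1.loc[gene_subset]
        d2 = d2.loc[gene_subset]

    opts = config.bicor_options()
    C1 = bicor_matrix(d1, opts)
    C2 = bicor_matrix(d2, opts)
    adj = drop_isolated_nodes(dual_threshold_adjacency(C1, C2, config.t1, config.t2))
    if adj.empty:
        logger.warning("thresholds t1=%s t2=%s leave no edges", config.t1, config.t2)
        cliques = []
    else:
        cliques = enumerate_cliques(
            adj, min_size=config.min_clique_size, maximal=not all_cliques
        )
    module = merge_cliques(cliques, adj)
    grid = np.round(np.linspace(0.1, 0.9, 9), 2)
    diagnostic = threshold_grid(C1, C2, grid, grid)

    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        with open(out_dir / "cliques.txt", "w") as fh:
            for c in cliques:
                fh.write("\t".join(map(str, c)) + "\n")
        pd.DataFrame(module.edges, columns=["gene_i", "gene_j"]).to_csv(
            out_dir / "module_edges.tsv", sep="\t", index=False
        )
        summary = {
            "n_cliques": len(cliques),
            "module_genes": list(module.nodes),
            "module_n_edges": len(module.edges),
            "module_density": module.density,
            "t1": config.t1,
            "t2": config.t2,
            "min_clique_size": config.min_clique_size,
        }
        (out_dir / "module.log").write_text(yaml.safe_dump(summary, sort_keys=False))
        diagnostic.to_csv(out_dir / "threshold_grid.tsv", sep="\t", index=False)
        if graphml and module.nodes:
            import networkx as nx

            g = nx.Graph()
            g.add_nodes_from(module.nodes)
            g.add_edges_from(module.edges)
            nx.write_graphml(g, out_dir / "module.graphml")
    return cliques, module, diagnostic


def select_genes(
    table: pd.DataFrame,
    top_fraction: float | None = None,
    p_cutoff: float | None = None,
) -> list:
    """Gene selection by top dc fraction and/or permutation p-value cutoff.

    When both rules are given a gene must satisfy both; ranks break the
    top-fraction cut deterministically.
    """
    if top_fraction is None and p_cutoff is None:
        raise ValueError("give top_fraction and/or p_cutoff")
    selected = table
    if top_fraction is not None:
        k = int(round(top_fraction * len(table)))
        selected = selected[selected["rank"] <= k]
    if p_cutoff is not None:
        selected = selected[selected["p_value"].notna() & (selected["p_value"] <= p_cutoff)]
    return list(selected.index)
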