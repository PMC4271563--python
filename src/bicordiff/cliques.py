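"""Dual-condition adjacency and clique-based gene modules.

A gene pair is connected when its coexpression is strong in one condition
(|corr| >= t1, e.g. normal) and weak in the other (|corr| <= t2, e.g.
disease) — an edge records coexpression that the disease state has lost.
Maximal cliques of at least a minimum size in the resulting binary graph are
mined (Bron-Kerbosch with pivoting) and merged into a gene module whose
density — edges over the complete-graph edge count — measures how close the
module is to a clique.

Threshold choice is left to the user; ``threshold_grid`` reports isolated-node
proportion and graph density over a grid of (t1, t2) as guidance, since too
strict a pair of thresholds empties the graph while too loose a pair yields
one overlapping blob.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from itertools import combinations

import networkx as nx
import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class GeneModule:
    """Merged clique module: node set, within-clique edge set, and density."""

    nodes: tuple
    edges: tuple
    density: float

    def __post_init__(self) -> None:
        node_set = set(self.nodes)
        for a, b in self.edges:
            if a not in node_set or b not in node_set:
                raise ValueError(f"edge ({a}, {b}) has endpoint outside the module")


def _check_aligned(C1: pd.DataFrame, C2: pd.DataFrame) -> None:
    if not C1.index.equals(C2.index) or not C1.columns.equals(C2.columns):
        raise ValueError("correlation matrices must share gene ids and ordering")


def dual_threshold_adjacency(
    C1: pd.DataFrame, C2: pd.DataFrame, t1: float, t2: float
) -> pd.DataFrame:
    """Binary adjacency: edge iff |C1(i,j)| >= t1 AND |C2(i,j)| <= t2, i != j.

    Comparisons are inclusive on both thresholds and use absolute
    correlations; missing correlations never form an edge.  The diagonal is 0
    (no self-loops).
    """
    _check_aligned(C1, C2)
    for name, t in (("t1", t1), ("t2", t2)):
        if not 0.0 <= t <= 1.0:
            raise ValueError(f"{name} must be in [0, 1], got {t}")
    V1 = np.abs(np.asarray(C1, dtype=float))
    V2 = np.abs(np.asarray(C2, dtype=float))
    with np.errstate(invalid="ignore"):
        adj = ((V1 >= t1) & (V2 <= t2)).astype(int)
    np.fill_diagonal(adj, 0)
    return pd.DataFrame(adj, index=C1.index, columns=C1.columns)


def drop_isolated_nodes(A: pd.DataFrame) -> pd.DataFrame:
    """Remove degree-0 nodes; returns the induced submatrix."""
    degree = np.asarray(A).sum(axis=1)
    keep = degree > 0
    if not keep.any():
        logger.warning("all %d nodes are isolated; returning empty graph", len(A))
    kept_ids = A.index[keep]
    return A.loc[kept_ids, kept_ids]


def enumerate_cliques(
    A: pd.DataFrame, min_size: int = 4, maximal: bool = True
) -> list[tuple]:
    """Cliques of size >= min_size, in deterministic lexicographic order.

    By default only MAXIMAL cliques are returned (Bron-Kerbosch with
    pivoting via networkx); listing every k-clique double-counts sub-cliques
    of larger ones.  ``maximal=False`` enumerates all cliques of the minimum
    size or larger, for comparison.
    """
    if min_size < 2:
        raise ValueError("min_size must be >= 2")
    G = nx.Graph()
    G.add_nodes_from(A.index)
    idx = list(A.index)
    arr = np.asarray(A)
    for i, j in zip(*np.nonzero(np.triu(arr, k=1))):
        G.add_edge(idx[i], idx[j])
    source = nx.find_cliques(G) if maximal else nx.enumerate_all_cliques(G)
    cliques = [tuple(sorted(c, key=str)) for c in source if len(c) >= min_size]
    return sorted(cliques, key=lambda c: tuple(map(str, c)))


def merge_cliques(cliques, A: pd.DataFrame) -> GeneModule:
    """Merge cliques into one module: union of nodes, union of in-clique edges.

    Raises if a clique contains a pair that is not an edge of ``A`` (corrupt
    input).  Density is |edges| / (|nodes| choose 2); an empty or single-node
    module has density 0.
    """
    arr = np.asarray(A)
    pos = {g: k for k, g in enumerate(A.index)}
    nodes: set = set()
    edges: set = set()
    for clique in cliques:
        for a, b in combinations(clique, 2):
            if a not in pos or b not in pos or not arr[pos[a], pos[b]]:
                raise ValueError(f"clique pair ({a}, {b}) is not an edge of the graph")
        nodes.update(clique)
        edges.update(tuple(sorted(pair, key=str)) for pair in combinations(clique, 2))
    k = len(nodes)
    max_edges = k * (k - 1) / 2
    density = len(edges) / max_edges if max_edges > 0 else 0.0
    return GeneModule(
        nodes=tuple(sorted(nodes, key=str)),
        edges=tuple(sorted(edges)),
        density=density,
    )


def threshold_grid(
    C1: pd.DataFrame, C2: pd.DataFrame, t1_values, t2_values
) -> pd.DataFrame:
    """Diagnostic over a (t1, t2) grid: edge count, density, isolated fraction.

    Guidance for threshold selection rather than automation; density here is
    of the whole thresholded graph, not of a mined module.
    """
    _check_aligned(C1, C2)
    G = len(C1)
    max_edges = G * (G - 1) / 2
    rows = []
    for t1 in t1_values:
        for t2 in t2_values:
            adj = np.asarray(dual_threshold_adjacency(C1, C2, t1, t2))
            n_edges = int(np.triu(adj, k=1).sum())
            isolated = float((adj.sum(axis=1) == 0).mean())
            rows.append((t1, t2, n_edges, n_edges / max_edges, isolated))
    return pd.DataFrame(
        rows, columns=["t1", "t2", "n_edges", "graph_density", "isolated_fraction"]
    )
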