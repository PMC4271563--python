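"""Shared fixtures and independent reference implementations (oracles).

The reference functions here are deliberately naive, literal transcriptions
of the defining formulas — loops and itertools instead of vectorised linear
algebra — so they stay independent of the code paths they check.
"""

from itertools import combinations

import numpy as np
import pandas as pd
import pytest


def ref_bicor(x, y):
    """Literal transcription of the biweight midcorrelation formulas."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    medx, medy = np.median(x), np.median(y)
    madx = np.median(np.abs(x - medx))
    mady = np.median(np.abs(y - medy))
    u = (x - medx) / (9 * madx)
    v = (y - medy) / (9 * mady)
    wx = (1 - u**2) ** 2 * (np.abs(u) < 1)
    wy = (1 - v**2) ** 2 * (np.abs(v) < 1)
    num = np.sum((x - medx) * wx * (y - medy) * wy)
    den = np.sqrt(np.sum(((x - medx) * wx) ** 2)) * np.sqrt(
        np.sum(((y - medy) * wy) ** 2)
    )
    return num / den


def ref_dc(x, y):
    """Root-mean-square coexpression change, written as an explicit sum."""
    x, y = list(x), list(y)
    return (sum((a - b) ** 2 for a, b in zip(x, y)) / len(x)) ** 0.5


def ref_dc_table(C1, C2, mask):
    """Per-gene dc by an explicit double loop over the mask."""
    genes = list(C1.index)
    out = {}
    for g in genes:
        neighbors = [h for h in genes if h != g and bool(mask.loc[g, h])]
        if not neighbors:
            out[g] = (float("nan"), 0)
        else:
            xs = [C1.loc[g, h] for h in neighbors]
            ys = [C2.loc[g, h] for h in neighbors]
            out[g] = (ref_dc(xs, ys), len(neighbors))
    return out


def ref_maximal_cliques(adj: np.ndarray, min_size: int):
    """Maximal cliques by exhaustive subset enumeration (graphs <= ~12 nodes)."""
    n = adj.shape[0]
    complete = []
    for size in range(min_size, n + 1):
        for subset in combinations(range(n), size):
            if all(adj[i, j] for i, j in combinations(subset, 2)):
                complete.append(frozenset(subset))
    maximal = [
        c for c in complete if not any(c < other for other in complete)
    ]
    return sorted(tuple(sorted(c)) for c in maximal)


def ref_bh(pvals):
    """BH step-up by the closed-form definition."""
    p = list(pvals)
    n = len(p)
    order = sorted(range(n), key=lambda i: p[i])
    q = [None] * n
    running_min = float("inf")
    for k in range(n - 1, -1, -1):
        i = order[k]
        running_min = min(running_min, p[i] * n / (k + 1))
        q[i] = min(running_min, 1.0)
    return q


@pytest.fixture
def rng():
    return np.random.default_rng(20240915)


@pytest.fixture
def small_expression(rng):
    """5 genes x 10 samples of seeded noise as a DataFrame."""
    data = rng.standard_normal((5, 10))
    return pd.DataFrame(
        data,
        index=[f"g{i}" for i in range(5)],
        columns=[f"s{j}" for j in range(10)],
    )


def random_correlation_pair(rng, n_genes=8):
    """Two symmetric correlation-like matrices with unit diagonal."""
    mats = []
    for _ in range(2):
        a = rng.uniform(-1, 1, size=(n_genes, n_genes))
        sym = np.clip((a + a.T) / 2, -1, 1)
        np.fill_diagonal(sym, 1.0)
        ids = [f"g{i}" for i in range(n_genes)]
        mats.append(pd.DataFrame(sym, index=ids, columns=ids))
    return mats
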