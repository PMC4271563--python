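"""Two-condition expression simulator with planted differential coexpression.

The generator emulates a small regulatory-module benchmark: a handful of
"planted" genes share a latent factor whose strength differs between the two
conditions, so their pairwise correlation is ~r1 in condition 1 and ~r2 in
condition 2, while the remaining genes are independent noise.  Each planted
gene is

    value = s * sqrt(|r|) * latent + sqrt(1 - |r|) * noise,

with s = +1 (alternating -1 across genes when the target r is negative, since
a single factor cannot give every pair the same negative correlation).  The
default conditions are the benchmark's: 20 genes, 50 samples per condition,
7 planted genes with within-module correlation 0.9 in condition 1 and 0 in
condition 2.

Optional gross outliers — entries replaced by deviates with a standard
deviation of ``outlier_magnitude`` — exercise the robustness of the biweight
midcorrelation downstream.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io import ExpressionMatrix


@dataclass(frozen=True)
class SimulationSpec:
    """Parameters of the planted-module simulation.

    All correlations are target values in [-1, 1]; ``outlier_rate`` is the
    fraction of matrix entries replaced, and ``outlier_magnitude`` the
    standard deviation (in units of the base noise SD) of the replacements.
    """

    n_genes: int = 20
    n_samples_per_condition: int = 50
    planted_gene_count: int = 7
    r_condition1: float = 0.9
    r_condition2: float = 0.0
    background_correlation: float = 0.0
    outlier_rate: float = 0.0
    outlier_magnitude: float = 5.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_genes < 1 or self.n_samples_per_condition < 1:
            raise ValueError("need at least 1 gene and 1 sample")
        if not 0 <= self.planted_gene_count <= self.n_genes:
            raise ValueError("planted_gene_count must be in [0, n_genes]")
        for name in ("r_condition1", "r_condition2", "background_correlation"):
            r = getattr(self, name)
            if not -1.0 <= r <= 1.0:
                raise ValueError(f"{name} must be in [-1, 1], got {r}")
        if not 0.0 <= self.outlier_rate <= 1.0:
            raise ValueError("outlier_rate must be in [0, 1]")
        if self.outlier_magnitude <= 0:
            raise ValueError("outlier_magnitude must be positive")

    @property
    def gene_ids(self) -> list[str]:
        return [f"g{i + 1:04d}" for i in range(self.n_genes)]

    @property
    def planted_genes(self) -> list[str]:
        """The first ``planted_gene_count`` gene ids carry the planted module."""
        return self.gene_ids[: self.planted_gene_count]


def _sample_ids(n: int) -> list[str]:
    return [f"s{i + 1:04d}" for i in range(n)]


def _correlated_block(rng, n_genes: int, n_samples: int, r: float) -> np.ndarray:
    """Single-factor block with pairwise correlation ~r between its genes."""
    latent = rng.standard_normal(n_samples)
    noise = rng.standard_normal((n_genes, n_samples))
    load = np.sqrt(abs(r))
    signs = np.ones(n_genes)
    if r < 0:
        signs[1::2] = -1.0
    return signs[:, None] * load * latent + np.sqrt(1.0 - abs(r)) * noise


def _one_condition(rng, spec: SimulationSpec, r_module: float) -> np.ndarray:
    n, m = spec.n_genes, spec.n_samples_per_condition
    k = spec.planted_gene_count
    X = np.empty((n, m))
    if k:
        X[:k] = _correlated_block(rng, k, m, r_module)
    n_bg = n - k
    if n_bg:
        if spec.background_correlation != 0.0:
            X[k:] = _correlated_block(rng, n_bg, m, spec.background_correlation)
        else:
            X[k:] = rng.standard_normal((n_bg, m))
    return X


def _inject_outliers(rng, X: np.ndarray, spec: SimulationSpec) -> np.ndarray:
    if spec.outlier_rate == 0.0:
        return X
    flat = X.ravel().copy()
    n_out = int(round(spec.outlier_rate * flat.size))
    if n_out:
        where = rng.choice(flat.size, size=n_out, replace=False)
        flat[where] = spec.outlier_magnitude * rng.standard_normal(n_out)
    return flat.reshape(X.shape)


def generate_condition_pair(spec: SimulationSpec):
    """Two-condition pair with the planted differential-coexpression module.

    Deterministic under ``spec.seed``; at ``outlier_rate=0`` the output is
    exactly the no-outlier dataset for the same seed.

    Returns
    -------
    (ExpressionMatrix, ExpressionMatrix)
        Condition 1 ("normal"-like) and condition 2 ("disease"-like).
    """
    rng = np.random.default_rng(spec.seed)
    X1 = _one_condition(rng, spec, spec.r_condition1)
    X2 = _one_condition(rng, spec, spec.r_condition2)
    X1 = _inject_outliers(rng, X1, spec)
    X2 = _inject_outliers(rng, X2, spec)
    samples = _sample_ids(spec.n_samples_per_condition)
    return (
        ExpressionMatrix(
            pd.DataFrame(X1, index=spec.gene_ids, columns=samples), "condition1"
        ),
        ExpressionMatrix(
            pd.DataFrame(X2, index=spec.gene_ids, columns=samples), "condition2"
        ),
    )


def generate_null_pair(spec: SimulationSpec):
    """Two conditions drawn from one independent-gene model (no planted effect).

    Every gene is i.i.d. standard normal in both conditions — the null under
    which the permutation test is calibrated.
    """
    rng = np.random.default_rng(spec.seed)
    n, m = spec.n_genes, spec.n_samples_per_condition
    X1 = rng.standard_normal((n, m))
    X2 = rng.standard_normal((n, m))
    samples = _sample_ids(m)
    return (
        ExpressionMatrix(
            pd.DataFrame(X1, index=spec.gene_ids, columns=samples), "condition1"
        ),
        ExpressionMatrix(
            pd.DataFrame(X2, index=spec.gene_ids, columns=samples), "condition2"
        ),
    )
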