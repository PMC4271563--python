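"""Biweight midcorrelation (bicor), a robust alternative to Pearson correlation.

Each expression profile is centred at its median and scaled by nine times its
median absolute deviation (MAD).  Points are then downweighted with the Tukey
biweight, ``w = (1 - u^2)^2`` for standardized deviations ``|u| < 1`` and zero
otherwise, so an observation further than nine MADs from the median contributes
nothing.  A handful of gross outliers therefore cannot dominate the correlation
the way they do for Pearson's r, which is why bicor is the similarity of choice
here for noisy microarray profiles.

The correlation itself is the Tukey-weighted analogue of Pearson's formula::

    bicor(x, y) = sum_i a_i b_i / sqrt(sum_j a_j^2) / sqrt(sum_k b_k^2)

with ``a_i = (x_i - med(x)) w_i(x)`` and likewise for ``b_i``.  Values lie in
[-1, 1]; -1 is maximal negative correlation, 1 maximal positive, 0 unrelated.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: Tukey biweight tuning constant: deviations beyond this many MADs get weight 0.
TUNING_CONSTANT = 9.0

#: Zero-MAD vectors fall back to mean/SD centring with unit weights (Pearson-like).
PEARSON_FALLBACK = "pearson_fallback"
#: Zero-MAD vectors yield NaN correlations, propagated downstream as non-informative.
UNDEFINED = "undefined"

_ZERO_MAD_POLICIES = (PEARSON_FALLBACK, UNDEFINED)


class ZeroMadError(ValueError):
    """Raised when a vector has zero median absolute deviation (degenerate scale)."""


@dataclass(frozen=True)
class BicorOptions:
    """Options controlling bicor's outlier and degenerate-vector handling.

    Parameters
    ----------
    max_p_outliers : float in (0, 1]
        Maximum allowed proportion of low and of high outliers, per side.  If
        below 1, each side of the standardized deviations is rescaled so that
        at most this proportion of points per side receives zero weight.  The
        default 1.0 disables capping (the bare median/9-MAD standardization).
    zero_mad_policy : {"pearson_fallback", "undefined"}
        What to do when a profile's MAD is zero. ``pearson_fallback`` replaces
        that vector's median/9-MAD standardization with mean centring and unit
        weights; ``undefined`` yields NaN correlations for that gene.
    """

    max_p_outliers: float = 1.0
    zero_mad_policy: str = PEARSON_FALLBACK

    def __post_init__(self) -> None:
        if not 0.0 < self.max_p_outliers <= 1.0:
            raise ValueError(
                f"max_p_outliers must be in (0, 1], got {self.max_p_outliers}"
            )
        if self.zero_mad_policy not in _ZERO_MAD_POLICIES:
            raise ValueError(
                f"zero_mad_policy must be one of {_ZERO_MAD_POLICIES}, "
                f"got {self.zero_mad_policy!r}"
            )


def _as_vector(x) -> np.ndarray:
    arr = np.asarray(x, dtype=float)
    if arr.ndim != 1:
        raise ValueError(f"expected a 1-D vector, got shape {arr.shape}")
    if arr.size == 0:
        raise ValueError("empty vector is degenerate")
    if not np.all(np.isfinite(arr)):
        raise ValueError("vector contains non-finite values")
    return arr


def robust_median(x) -> float:
    """Sample median; even length averages the two central order statistics."""
    return float(np.median(_as_vector(x)))


def robust_mad(x) -> float:
    """Unscaled median absolute deviation: med(|x_i - med(x)|).

    No normal-consistency factor is applied; the bicor standardization absorbs
    scale through the factor 9 directly.
    """
    arr = _as_vector(x)
    return float(np.median(np.abs(arr - np.median(arr))))


def _cap_sides(u: np.ndarray, max_p_outliers: float) -> np.ndarray:
    """Rescale each side of u so at most max_p_outliers per side has |u| >= 1.

    Uses the empirical quantiles of u at ``max_p_outliers`` (lower side) and
    ``1 - max_p_outliers`` (upper side); a side whose quantile exceeds 1 in
    magnitude is divided by that magnitude.  Works on a 2-D row-per-gene array.
    """
    if max_p_outliers >= 1.0:
        return u
    lo = np.quantile(u, max_p_outliers, axis=-1, keepdims=True)
    hi = np.quantile(u, 1.0 - max_p_outliers, axis=-1, keepdims=True)
    neg_scale = np.where(lo < -1.0, -lo, 1.0)
    pos_scale = np.where(hi > 1.0, hi, 1.0)
    return np.where(u < 0.0, u / neg_scale, u / pos_scale)


def standardized_scores(x, opts: BicorOptions | None = None) -> np.ndarray:
    """Median/9-MAD standardized deviations u_i = (x_i - med(x)) / (9 mad(x)).

    Raises
    ------
    ZeroMadError
        If the vector's MAD is zero; the caller applies the zero-MAD policy.
    """
    opts = opts or BicorOptions()
    arr = _as_vector(x)
    med = np.median(arr)
    mad = np.median(np.abs(arr - med))
    if mad == 0.0:
        raise ZeroMadError("vector has zero MAD; standardization undefined")
    u = (arr - med) / (TUNING_CONSTANT * mad)
    return _cap_sides(u, opts.max_p_outliers)


def bicor_weight(u):
    """Tukey biweight w = (1 - u^2)^2 I(|u| < 1); zero at and beyond |u| = 1."""
    u = np.asarray(u, dtype=float)
    w = (1.0 - u**2) ** 2 * (np.abs(u) < 1.0)
    return float(w) if w.ndim == 0 else w


def _weighted_deviation_rows(X: np.ndarray, opts: BicorOptions):
    """Per-row weighted deviations a_i = (x_i - med) w_i for a genes x samples array.

    Returns ``(a, zero_mad)`` where ``zero_mad`` flags rows whose MAD is zero.
    Those rows are mean-centred with unit weights under the Pearson fallback;
    under the ``undefined`` policy the caller should NaN them out.
    """
    med = np.median(X, axis=-1, keepdims=True)
    abs_dev = np.abs(X - med)
    mad = np.median(abs_dev, axis=-1, keepdims=True)
    zero_mad = mad[..., 0] == 0.0
    safe_mad = np.where(mad == 0.0, 1.0, mad)
    u = (X - med) / (TUNING_CONSTANT * safe_mad)
    u = _cap_sides(u, opts.max_p_outliers)
    w = (1.0 - u**2) ** 2 * (np.abs(u) < 1.0)
    a = (X - med) * w
    if np.any(zero_mad):
        fallback = X[zero_mad] - X[zero_mad].mean(axis=-1, keepdims=True)
        a[zero_mad] = fallback
    return a, zero_mad


def bicor(x, y, opts: BicorOptions | None = None) -> float:
    """Biweight midcorrelation of two equal-length vectors.

    Symmetric in its arguments, invariant under per-vector increasing affine
    transforms, and bounded in [-1, 1].  Returns NaN when a correlation is
    undefined (zero-MAD vector under the ``undefined`` policy, or weights that
    remove all variation).
    """
    opts = opts or BicorOptions()
    xv = _as_vector(x)
    yv = _as_vector(y)
    if xv.size != yv.size:
        raise ValueError(f"length mismatch: {xv.size} vs {yv.size}")
    if xv.size < 2:
        raise ValueError("need at least 2 observations")
    a, zx = _weighted_deviation_rows(xv[None, :], opts)
    b, zy = _weighted_deviation_rows(yv[None, :], opts)
    if opts.zero_mad_policy == UNDEFINED and (zx[0] or zy[0]):
        return float("nan")
    na = float(np.sqrt(a[0] @ a[0]))
    nb = float(np.sqrt(b[0] @ b[0]))
    if na == 0.0 or nb == 0.0:
        # All weighted deviations vanished: no variation left to correlate.
        return float("nan")
    r = float(a[0] @ b[0]) / (na * nb)
    return float(np.clip(r, -1.0, 1.0))


def bicor_matrix(
    expression: pd.DataFrame, opts: BicorOptions | None = None
) -> pd.DataFrame:
    """Pairwise bicor matrix for a genes x samples expression table.

    Parameters
    ----------
    expression : DataFrame
        Rows are genes (unique identifiers in the index), columns samples.
    opts : BicorOptions, optional

    Returns
    -------
    DataFrame
        Symmetric gene x gene correlation matrix, diagonal 1 for genes with a
        defined correlation; zero-MAD genes are handled per the policy and
        logged.
    """
    opts = opts or BicorOptions()
    if expression.index.has_duplicates:
        dupes = expression.index[expression.index.duplicated()].unique().tolist()
        raise ValueError(f"duplicate gene identifiers: {dupes[:10]}")
    X = np.asarray(expression, dtype=float)
    if X.shape[0] < 2 or X.shape[1] < 2:
        raise ValueError(f"need at least 2 genes and 2 samples, got {X.shape}")
    if not np.all(np.isfinite(X)):
        raise ValueError("expression matrix contains non-finite values")

    a, zero_mad = _weighted_deviation_rows(X, opts)
    if np.any(zero_mad):
        names = expression.index[zero_mad].tolist()
        logger.warning(
            "%d gene(s) with zero MAD handled per policy %r: %s",
            len(names), opts.zero_mad_policy, names[:10],
        )
    norms = np.sqrt(np.einsum("ij,ij->i", a, a))
    undefined = norms == 0.0
    if opts.zero_mad_policy == UNDEFINED:
        undefined = undefined | zero_mad
    safe = np.where(undefined, 1.0, norms)
    A = a / safe[:, None]
    C = np.clip(A @ A.T, -1.0, 1.0)
    np.fill_diagonal(C, 1.0)
    C[undefined, :] = np.nan
    C[:, undefined] = np.nan
    return pd.DataFrame(C, index=expression.index, columns=expression.index)
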