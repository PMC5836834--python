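"""Quantile normalization against a smoothed average reference, plus profile z-scoring.

Every sample (array) is forced to share one empirical distribution:
``x_norm = F2^{-1}(G(x))``, where ``G`` is the sample's own distribution
function and ``F2`` the reference.  The reference is the mean of the samples'
order statistics, optionally smoothed with a seven-point Savitzky-Golay
filter so the estimated quantile function is not dominated by order-statistic
noise.  After normalization each gene profile is z-scored (sample sd, n-1
denominator) so that phase assignment compares shapes, not magnitudes.
"""

from __future__ import annotations

import logging

import numpy as np
from scipy import signal, stats
from sklearn.base import BaseEstimator, TransformerMixin

from .datatypes import ExpressionMatrix

logger = logging.getLogger(__name__)


def compute_reference(values: np.ndarray) -> np.ndarray:
    """Average of the samples' order statistics (one entry per gene rank).

    Entry ``k`` is the mean over samples of each sample's k-th smallest
    value; the result is non-decreasing by construction.
    """
    values = np.asarray(values, dtype=float)
    if values.ndim != 2 or values.size == 0:
        raise ValueError("expected a non-empty 2-D matrix")
    return np.sort(values, axis=0).mean(axis=1)


def smooth_reference(ref: np.ndarray, window: int = 7, polyorder: int = 2) -> np.ndarray:
    """Savitzky-Golay smoothing of the reference quantile function.

    Boundary windows are handled by polynomial fit (``mode='interp'``).  The
    output is re-sorted ascending: the reference acts as an inverse
    distribution function and must stay non-decreasing even if smoothing
    induces local inversions.  Inputs shorter than the window are returned
    unchanged with a warning.
    """
    ref = np.asarray(ref, dtype=float)
    if window % 2 != 1:
        raise ValueError("window must be odd")
    if polyorder >= window:
        raise ValueError("polyorder must be smaller than window")
    if ref.size < window:
        logger.warning(
            "smooth_reference: length %d < window %d, returning unsmoothed reference",
            ref.size,
            window,
        )
        return ref.copy()
    out = signal.savgol_filter(ref, window_length=window, polyorder=polyorder, mode="interp")
    return np.sort(out)


def quantile_normalize(values: np.ndarray, ref: np.ndarray) -> np.ndarray:
    """Replace each sample's values by rank-matched reference values.

    Ties get average ranks and hence averaged reference values (linear
    interpolation between adjacent order statistics), keeping the map
    monotone and deterministic.  For tie-free columns the sorted values of
    every output column equal ``ref`` exactly.
    """
    values = np.asarray(values, dtype=float)
    ref = np.asarray(ref, dtype=float)
    if values.shape[0] != ref.size:
        raise ValueError("reference length must equal the number of genes")
    n = ref.size
    out = np.empty_like(values)
    grid = np.arange(1, n + 1, dtype=float)
    for j in range(values.shape[1]):
        ranks = stats.rankdata(values[:, j], method="average")
        out[:, j] = np.interp(ranks, grid, ref)
    return out


def zscore_profiles(values: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Row-wise z-scores (mean 0, sample sd 1) and a kept-row mask.

    Constant rows carry no phase information and cannot be scaled; they are
    excluded from the output (mask False) and their count logged.
    """
    values = np.asarray(values, dtype=float)
    sd = values.std(axis=1, ddof=1)
    keep = sd > 0
    n_dropped = int((~keep).sum())
    if n_dropped:
        logger.info("zscore_profiles: excluded %d constant profiles", n_dropped)
    centered = values[keep] - values[keep].mean(axis=1, keepdims=True)
    return centered / sd[keep, None], keep


class QuantileNormalizer(BaseEstimator, TransformerMixin):
    """Quantile normalization to a smoothed average reference distribution.

    ``fit`` estimates the reference from the matrix (genes x samples);
    ``transform`` substitutes rank-matched reference values within each
    sample column.  The reference is tied to the gene dimension, so
    ``transform`` requires the same number of rows as ``fit``.

    Parameters
    ----------
    smooth : bool
        Apply Savitzky-Golay smoothing to the reference (default True).
    window, polyorder : int
        Savitzky-Golay window length (odd, default 7) and polynomial order
        (default 2; order 2 reproduces linear trends exactly).

    Attributes
    ----------
    reference_ : ndarray of shape (n_genes,)
        Smoothed, non-decreasing reference quantile function.
    """

    def __init__(self, smooth: bool = True, window: int = 7, polyorder: int = 2):
        self.smooth = smooth
        self.window = window
        self.polyorder = polyorder

    def fit(self, X, y=None):
        X = np.asarray(X, dtype=float)
        ref = compute_reference(X)
        if self.smooth:
            ref = smooth_reference(ref, window=self.window, polyorder=self.polyorder)
        self.reference_ = ref
        self.n_genes_ = X.shape[0]
        return self

    def transform(self, X):
        if not hasattr(self, "reference_"):
            raise RuntimeError("QuantileNormalizer is not fitted")
        X = np.asarray(X, dtype=float)
        if X.shape[0] != self.n_genes_:
            raise ValueError(
                f"transform expects {self.n_genes_} rows (genes) as seen in fit, got {X.shape[0]}"
            )
        return quantile_normalize(X, self.reference_)


def normalize_matrix(
    matrix: ExpressionMatrix,
    *,
    smooth: bool = True,
    window: int = 7,
    polyorder: int = 2,
) -> tuple[ExpressionMatrix, np.ndarray]:
    """Full normalization stage: reference -> smooth -> quantile -> z-score.

    Returns the z-scored matrix (constant profiles dropped) and the boolean
    kept-row mask aligned to the input gene order.
    """
    qn = QuantileNormalizer(smooth=smooth, window=window, polyorder=polyorder)
    normalized = qn.fit_transform(matrix.values)
    z, keep = zscore_profiles(normalized)
    kept_ids = [g for g, k in zip(matrix.gene_ids, keep) if k]
    return ExpressionMatrix(kept_ids, z, matrix.design), keep
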