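"""Permutation gate on circadian-frequency spectral power (pt-test).

Profiles are tested for concentration of variance at exactly one frequency —
one cycle per 24 h on the sampling grid.  The null distribution is obtained
by shuffling the time order of the profile: shuffling preserves the value
multiset (total spectral power) but destroys its temporal arrangement, so
the circadian-frequency share of the power collapses to its exchangeable
baseline.  Significance is judged per profile without FDR correction: all
profiles are probed for the manifestation of one shared circadian factor,
not a family of independent hypotheses.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator

from .datatypes import ExpressionMatrix, TimeDesign

logger = logging.getLogger(__name__)


class InsufficientResolutionError(ValueError):
    """The sampling design cannot resolve the circadian frequency."""


def _circadian_exponential(design: TimeDesign) -> np.ndarray:
    n = design.n_samples
    f = int(design.n_cycles)  # DFT index of the 24-h frequency
    return np.exp(-2j * np.pi * f * np.arange(n) / n)


def circadian_power(profile: np.ndarray, design: TimeDesign) -> float:
    """Periodogram power |X(f*)|^2 / n at the circadian frequency.

    ``f*`` is the DFT bin completing ``n_cycles`` oscillations over the
    record, i.e. a 24-h period.  A single-cycle design needs at least four
    samples for this bin to be meaningfully resolvable.
    """
    profile = np.asarray(profile, dtype=float)
    _check_resolution(design)
    if profile.shape[-1] != design.n_samples:
        raise ValueError("profile length must equal the design's sample count")
    coef = profile @ _circadian_exponential(design)
    return float(np.abs(coef) ** 2 / design.n_samples)


def circadian_power_matrix(values: np.ndarray, design: TimeDesign) -> np.ndarray:
    """Vectorized :func:`circadian_power` over rows."""
    _check_resolution(design)
    values = np.asarray(values, dtype=float)
    coef = values @ _circadian_exponential(design)
    return np.abs(coef) ** 2 / design.n_samples


def _check_resolution(design: TimeDesign) -> None:
    if design.n_cycles == 1 and design.n_samples < 4:
        raise InsufficientResolutionError(
            "a single-cycle design needs at least 4 samples to resolve the "
            "circadian frequency"
        )


def pt_test(
    profile: np.ndarray,
    design: TimeDesign,
    n_permutations: int = 999,
    rng: np.random.Generator | int | None = None,
) -> float:
    """Permutation p-value for circadian-frequency power.

    ``p = (1 + #{permutations with power >= observed}) / (B + 1)`` where each
    of the B permutations shuffles the profile's time order uniformly at
    random.  The +1 terms make the p-value exact-level and bounded below by
    ``1/(B+1)``.
    """
    if n_permutations < 99:
        raise ValueError("n_permutations must be at least 99")
    rng = np.random.default_rng(rng)
    profile = np.asarray(profile, dtype=float)
    observed = circadian_power(profile, design)
    idx = np.tile(np.arange(design.n_samples), (n_permutations, 1))
    idx = rng.permuted(idx, axis=1)
    powers = circadian_power_matrix(profile[idx], design)
    n_ge = int(np.sum(powers >= observed - 1e-12))
    return (1 + n_ge) / (n_permutations + 1)


class PeriodicityFilter(BaseEstimator):
    """Row filter keeping profiles with permutation-significant circadian power.

    scikit-learn-style selector operating on a genes x samples matrix:
    ``fit`` computes per-gene circadian power and permutation p-values,
    ``get_support`` returns the kept-gene mask, ``transform`` the kept rows.
    Per-gene permutation streams are spawned from ``random_state`` by row
    index, so results do not depend on processing order.

    Parameters
    ----------
    design : TimeDesign
    alpha : float
        Retention threshold on the permutation p-value (default 0.05),
        applied without multiplicity correction by design.
    n_permutations : int
        Number of time-order shuffles per gene (default 999).
    random_state : int or None
        Seed for the permutation streams.
    """

    def __init__(
        self,
        design: TimeDesign | None = None,
        alpha: float = 0.05,
        n_permutations: int = 999,
        random_state: int | None = None,
    ):
        self.design = design
        self.alpha = alpha
        self.n_permutations = n_permutations
        self.random_state = random_state

    def fit(self, X, y=None):
        if self.design is None:
            raise ValueError("PeriodicityFilter requires a TimeDesign")
        if not 0.0 < self.alpha <= 1.0:
            raise ValueError("alpha must lie in (0, 1]")
        X = np.asarray(X, dtype=float)
        seeds = np.random.SeedSequence(self.random_state).spawn(X.shape[0])
        self.power_ = circadian_power_matrix(X, self.design)
        p = np.empty(X.shape[0])
        for i in range(X.shape[0]):
            p[i] = pt_test(
                X[i],
                self.design,
                n_permutations=self.n_permutations,
                rng=np.random.default_rng(seeds[i]),
            )
        self.p_perm_ = p
        # alpha == 1 disables the gate entirely (p can legitimately equal 1)
        self.support_ = p < self.alpha if self.alpha < 1.0 else np.ones(len(p), dtype=bool)
        return self

    def get_support(self) -> np.ndarray:
        if not hasattr(self, "support_"):
            raise RuntimeError("PeriodicityFilter is not fitted")
        return self.support_

    def transform(self, X):
        X = np.asarray(X, dtype=float)
        return X[self.get_support()]


def periodicity_table(
    matrix: ExpressionMatrix,
    alpha: float = 0.05,
    n_permutations: int = 999,
    random_state: int | None = None,
) -> pd.DataFrame:
    """Per-gene circadian power and permutation p-value as a DataFrame."""
    filt = PeriodicityFilter(
        design=matrix.design,
        alpha=alpha,
        n_permutations=n_permutations,
        random_state=random_state,
    ).fit(matrix.values)
    return pd.DataFrame(
        {
            "gene_id": matrix.gene_ids,
            "power": filt.power_,
            "p_perm": filt.p_perm_,
            "kept": filt.support_,
        }
    )


def filter_oscillating(
    matrix: ExpressionMatrix,
    alpha: float = 0.05,
    n_permutations: int = 999,
    random_state: int | None = None,
) -> list[str]:
    """Gene ids whose permutation p-value falls below ``alpha`` (uncorrected)."""
    table = periodicity_table(
        matrix, alpha=alpha, n_permutations=n_permutations, random_state=random_state
    )
    kept = table.loc[table["kept"], "gene_id"].tolist()
    logger.info("filter_oscillating: kept %d of %d genes at alpha=%g", len(kept), matrix.n_genes, alpha)
    return kept
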