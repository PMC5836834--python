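"""Shared domain types for circadian time-course analysis.

The pipeline operates on expression profiles sampled at regular zeitgeber
times over one or more 24-h cycles.  A :class:`TimeDesign` fixes the sampling
geometry and thereby the number of discrete phases a gene can be assigned to
(one phase per sample-collection time within the period).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np


class DesignMismatchError(ValueError):
    """Input table shape or labels do not match the sampling design."""


class ExpressionParseError(ValueError):
    """A cell or header of an expression table could not be parsed."""


class GMTParseError(ValueError):
    """A line of a GMT annotation file is malformed."""


@dataclass(frozen=True)
class TimeDesign:
    """Sampling design of a diurnal time course.

    Parameters
    ----------
    period_h : float
        Length of one cycle in hours (24 for a circadian design).
    interval_h : float
        Spacing between consecutive samples in hours.  Must divide
        ``period_h`` exactly so that the phase bins tile the period.
    n_cycles : int
        Number of complete cycles sampled.

    With 3-h sampling of a 24-h period there are 8 phases; with 4-h sampling
    there are 6.  Each phase's peak coincides with a sample-collection time.
    """

    period_h: float = 24.0
    interval_h: float = 4.0
    n_cycles: int = 2

    def __post_init__(self) -> None:
        if self.period_h <= 0 or self.interval_h <= 0:
            raise ValueError("period_h and interval_h must be positive")
        if int(self.n_cycles) != self.n_cycles or self.n_cycles < 1:
            raise ValueError("n_cycles must be a positive integer")
        ratio = self.period_h / self.interval_h
        if abs(ratio - round(ratio)) > 1e-9:
            raise ValueError(
                f"interval_h={self.interval_h} does not divide period_h={self.period_h}; "
                "phase bins must tile the period exactly"
            )

    @property
    def n_phases(self) -> int:
        """Number of discrete phases (samples per cycle)."""
        return round(self.period_h / self.interval_h)

    @property
    def n_samples(self) -> int:
        return self.n_phases * int(self.n_cycles)

    @property
    def sample_times(self) -> np.ndarray:
        """Zeitgeber hours of the samples, strictly increasing."""
        return np.arange(self.n_samples) * self.interval_h

    def wrap_time(self, t: float | np.ndarray) -> np.ndarray | float:
        """Wrap hours into the half-open cycle [0, period_h)."""
        return np.mod(t, self.period_h)

    def circular_distance_h(self, a, b):
        """Shortest distance in hours around the cycle between times a and b."""
        d = np.mod(np.abs(np.asarray(a, dtype=float) - np.asarray(b, dtype=float)), self.period_h)
        return np.minimum(d, self.period_h - d)

    def phase_peak_time(self, phase_index: int) -> float:
        if not 0 <= phase_index < self.n_phases:
            raise ValueError(f"phase_index {phase_index} out of range [0, {self.n_phases})")
        return phase_index * self.interval_h

    def phase_confidence_interval(self, phase_index: int) -> tuple[float, float]:
        """Wrapped confidence interval around a phase's peak.

        The interval spans one sampling interval on either side of the peak,
        so it covers ``2 * interval_h`` in total (6 h for 3-h sampling, 8 h
        for 4-h sampling).  Endpoints are reported wrapped into
        ``[0, period_h)``: the phase peaking at ZT0 under 3-h sampling has
        interval (21, 3).
        """
        peak = self.phase_peak_time(phase_index)
        lo = float(self.wrap_time(peak - self.interval_h))
        hi = float(self.wrap_time(peak + self.interval_h))
        return lo, hi


@dataclass
class ExpressionMatrix:
    """Gene-by-sample expression values tied to a :class:`TimeDesign`.

    Rows are genes (or probes), columns are samples ordered by the design's
    zeitgeber times.  Values must be complete (no NaN) — every downstream
    statistic assumes full profiles.
    """

    gene_ids: list[str]
    values: np.ndarray
    design: TimeDesign

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.gene_ids = [str(g) for g in self.gene_ids]
        if self.values.ndim != 2:
            raise ValueError("values must be a 2-D matrix")
        if len(self.gene_ids) != self.values.shape[0]:
            raise ValueError("gene_ids length must equal number of rows")
        if len(self.gene_ids) == 0:
            raise ValueError("matrix must contain at least one gene")
        if len(set(self.gene_ids)) != len(self.gene_ids):
            raise ValueError("gene_ids must be unique")
        if self.values.shape[1] != self.design.n_samples:
            raise DesignMismatchError(
                f"matrix has {self.values.shape[1]} columns but the design "
                f"defines {self.design.n_samples} samples"
            )
        if not np.all(np.isfinite(self.values)):
            raise ValueError("expression values must be finite (no missing values)")

    @property
    def n_genes(self) -> int:
        return self.values.shape[0]

    def to_frame(self):
        import pandas as pd

        cols = [f"ZT{t:g}" for t in self.design.sample_times]
        return pd.DataFrame(self.values, index=self.gene_ids, columns=cols)

    def select(self, gene_ids: Iterable[str]) -> "ExpressionMatrix":
        """Row subset in the given order; unknown ids raise KeyError."""
        index = {g: i for i, g in enumerate(self.gene_ids)}
        wanted = [str(g) for g in gene_ids]
        missing = [g for g in wanted if g not in index]
        if missing:
            raise KeyError(f"gene ids not in matrix: {missing[:5]}")
        rows = [index[g] for g in wanted]
        return ExpressionMatrix(wanted, self.values[rows], self.design)


@dataclass(frozen=True)
class GeneSetAnnotation:
    """Term -> gene-set mapping over a fixed background universe."""

    terms: Mapping[str, tuple[str, frozenset]]
    universe: frozenset

    def __post_init__(self) -> None:
        for term_id, (_, genes) in self.terms.items():
            if not genes:
                raise ValueError(f"term {term_id!r} has an empty gene set")
            if not genes <= self.universe:
                raise ValueError(f"term {term_id!r} contains genes outside the universe")

    @property
    def term_ids(self) -> list[str]:
        return sorted(self.terms)

    def genes_of(self, term_id: str) -> frozenset:
        return self.terms[term_id][1]

    def name_of(self, term_id: str) -> str:
        return self.terms[term_id][0]


@dataclass(frozen=True)
class PhaseAssignment:
    """Phase call for one gene.

    ``peak_time_h`` is the zeitgeber hour of the assigned phase's peak
    (``phase_index * interval_h``); ``correlation`` is the maximum Pearson
    correlation over the cosine template bank; ``confidence_p`` is the
    bootstrap confidence p-value (small = stable call).
    """

    gene_id: str
    phase_index: int
    peak_time_h: float
    correlation: float
    confidence_p: float

    def __post_init__(self) -> None:
        if not -1.0 - 1e-9 <= self.correlation <= 1.0 + 1e-9:
            raise ValueError("correlation must lie in [-1, 1]")
        if not 0.0 <= self.confidence_p <= 1.0:
            raise ValueError("confidence_p must lie in [0, 1]")
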