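"""Synthetic diurnal expression data with known oscillation and enrichment truth.

The generator emulates a microarray time course over normally cycling
tissue: a fraction of genes carries a cosine-shaped diurnal baseline of
known amplitude and peak time on top of a constant baseline, everything is
blurred with i.i.d. Gaussian noise, and an annotation file is built with
terms deliberately tilted toward genes peaking in chosen phases.  Every
downstream stage can therefore be scored against ground truth.

Default conditions mirror a 4-h sampling of two 24-h cycles (12 samples,
6 phases).  Amplitudes are drawn log-uniform so the gene population spans
low- and high-signal-to-noise regimes, as real arrays do across the whole
expression range; baselines are uniform on a log2-intensity-like scale.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .datatypes import ExpressionMatrix, GeneSetAnnotation, TimeDesign

DEFAULT_DESIGN = TimeDesign(period_h=24.0, interval_h=4.0, n_cycles=2)


def generate_expression(
    design: TimeDesign = DEFAULT_DESIGN,
    n_genes: int = 2000,
    frac_oscillating: float = 0.5,
    amp_range: tuple[float, float] = (0.5, 4.0),
    noise_sd: float = 0.5,
    baseline_range: tuple[float, float] = (6.0, 12.0),
    seed: int | np.random.Generator | None = None,
    phase_on_grid: bool = True,
) -> tuple[ExpressionMatrix, pd.DataFrame]:
    """Simulate a gene x time-point expression matrix with known truth.

    Oscillating gene i follows
    ``x_i(t) = baseline_i + A_i * cos(2*pi*(t - phi_i)/period_h) + eps``
    with ``eps ~ Normal(0, noise_sd^2)`` i.i.d. across time points;
    non-oscillating genes are baseline plus noise (amplitude 0).  Peak times
    ``phi_i`` sit on the sampling grid when ``phase_on_grid`` is true,
    otherwise uniform in ``[0, period_h)``.

    Returns the matrix and a truth table with one row per gene:
    ``gene_id, oscillating, true_phase_h, amplitude, baseline, noise_sd``
    (``true_phase_h`` is NaN for flat genes).
    """
    if n_genes < 1:
        raise ValueError("n_genes must be at least 1")
    if not 0.0 <= frac_oscillating <= 1.0:
        raise ValueError("frac_oscillating must lie in [0, 1]")
    if noise_sd <= 0:
        raise ValueError("noise_sd must be positive")
    if not 0 < amp_range[0] <= amp_range[1]:
        raise ValueError("amp_range must be positive and ordered")
    rng = np.random.default_rng(seed)

    n_osc = int(round(frac_oscillating * n_genes))
    oscillating = np.zeros(n_genes, dtype=bool)
    oscillating[:n_osc] = True

    amplitude = np.zeros(n_genes)
    amplitude[:n_osc] = np.exp(
        rng.uniform(np.log(amp_range[0]), np.log(amp_range[1]), size=n_osc)
    )
    baseline = rng.uniform(baseline_range[0], baseline_range[1], size=n_genes)
    phase = np.full(n_genes, np.nan)
    if phase_on_grid:
        phase[:n_osc] = rng.integers(design.n_phases, size=n_osc) * design.interval_h
    else:
        phase[:n_osc] = rng.uniform(0.0, design.period_h, size=n_osc)

    t = design.sample_times
    signal = np.zeros((n_genes, design.n_samples))
    signal[:n_osc] = amplitude[:n_osc, None] * np.cos(
        2 * np.pi * (t[None, :] - phase[:n_osc, None]) / design.period_h
    )
    values = baseline[:, None] + signal + rng.normal(scale=noise_sd, size=(n_genes, design.n_samples))

    width = len(str(n_genes))
    gene_ids = [f"g{i:0{width}d}" for i in range(n_genes)]
    truth = pd.DataFrame(
        {
            "gene_id": gene_ids,
            "oscillating": oscillating,
            "true_phase_h": phase,
            "amplitude": amplitude,
            "baseline": baseline,
            "noise_sd": noise_sd,
        }
    )
    return ExpressionMatrix(gene_ids, values, design), truth


def generate_annotation(
    truth: pd.DataFrame,
    design: TimeDesign = DEFAULT_DESIGN,
    n_terms: int = 50,
    genes_per_term: int = 25,
    planted: list[tuple[int, float]] | None = None,
    seed: int | np.random.Generator | None = None,
) -> tuple[GeneSetAnnotation, pd.DataFrame]:
    """Build an annotation with terms tilted toward chosen phases.

    ``planted`` lists ``(target_phase_index, excess_fraction)`` pairs; the
    first ``len(planted)`` terms draw a Binomial(genes_per_term,
    excess_fraction) share of their genes from oscillating genes whose true
    peak sits in the target phase bin and the remainder uniformly from the
    rest of the universe.  Remaining terms sample uniformly from the whole
    universe.  The universe is every gene in the truth table.

    Returns the annotation and an enrichment-truth table with one row per
    term: ``term_id, planted, target_phase_index, excess_fraction``.
    """
    planted = list(planted or [])
    if genes_per_term < 2:
        raise ValueError("genes_per_term must be at least 2")
    universe = truth["gene_id"].astype(str).to_numpy()
    if genes_per_term > len(universe):
        raise ValueError("genes_per_term exceeds the universe size")
    if n_terms < len(planted):
        raise ValueError("n_terms must cover all planted terms")
    for phase_idx, excess in planted:
        if not 0 <= phase_idx < design.n_phases:
            raise ValueError(f"target phase {phase_idx} invalid for the design")
        if not 0.0 < excess <= 1.0:
            raise ValueError("excess_fraction must lie in (0, 1]")
    rng = np.random.default_rng(seed)

    osc_phase_idx = np.full(len(universe), -1)
    is_osc = truth["oscillating"].to_numpy()
    if is_osc.any():
        wrapped = np.mod(truth.loc[is_osc, "true_phase_h"].to_numpy(), design.period_h)
        # nearest sampling time = phase bin of the true peak
        osc_phase_idx[is_osc] = (
            np.rint(wrapped / design.interval_h).astype(int) % design.n_phases
        )

    terms: dict[str, tuple[str, frozenset]] = {}
    rows = []
    width = len(str(max(n_terms, 1)))
    for i in range(n_terms):
        term_id = f"T{i:0{width}d}"
        if i < len(planted):
            target, excess = planted[i]
            pool = universe[osc_phase_idx == target]
            k_target = min(rng.binomial(genes_per_term, excess), len(pool))
            chosen = list(rng.choice(pool, size=k_target, replace=False))
            rest = np.setdiff1d(universe, chosen, assume_unique=False)
            chosen += list(rng.choice(rest, size=genes_per_term - k_target, replace=False))
            name = f"planted phase {target}"
            rows.append(
                {
                    "term_id": term_id,
                    "planted": True,
                    "target_phase_index": target,
                    "excess_fraction": excess,
                }
            )
        else:
            chosen = list(rng.choice(universe, size=genes_per_term, replace=False))
            name = "background term"
            rows.append(
                {
                    "term_id": term_id,
                    "planted": False,
                    "target_phase_index": -1,
                    "excess_fraction": 0.0,
                }
            )
        terms[term_id] = (name, frozenset(chosen))

    annotation = GeneSetAnnotation(terms=terms, universe=frozenset(universe))
    return annotation, pd.DataFrame(
        rows, columns=["term_id", "planted", "target_phase_index", "excess_fraction"]
    )
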