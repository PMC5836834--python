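"""End-to-end orchestration: simulate -> normalize -> filter -> phase -> enrich.

A single :class:`RunConfig` (loadable from YAML) drives every stage; a
manifest recording the seed, all parameters and the package version is
written before any result so that a run can be replayed bit-identically.
Each stage writes to a ``.partial`` file that is renamed into place only on
success, so an aborted run leaves its incomplete outputs clearly marked.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import os
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from . import __version__
from .datatypes import TimeDesign
from .enrichment import enrichment_wide, phase_enrichment_table, term_abundance_report
from .io import (
    read_expression,
    read_gmt,
    write_assignments,
    write_enrichment,
    write_expression,
    write_gmt,
)
from .normalize import normalize_matrix
from .periodicity import periodicity_table
from .phase import assign_matrix, select_confident
from .simulate import generate_annotation, generate_expression

logger = logging.getLogger(__name__)


class StageError(RuntimeError):
    """A pipeline stage failed; the message names the stage and cause."""


@dataclass
class RunConfig:
    """All knobs of a full pipeline run (see the methods note for rationale)."""

    seed: int = 0
    # sampling design
    period_h: float = 24.0
    interval_h: float = 4.0
    n_cycles: int = 2
    # synthetic data (used when no expression_path is given)
    n_genes: int = 2000
    frac_oscillating: float = 0.5
    amp_range: tuple[float, float] = (0.5, 4.0)
    noise_sd: float = 0.5
    baseline_range: tuple[float, float] = (6.0, 12.0)
    phase_on_grid: bool = True
    n_terms: int = 50
    genes_per_term: int = 25
    planted: list[tuple[int, float]] = field(default_factory=lambda: [(0, 0.8), (3, 0.8)])
    # normalization
    smooth_reference: bool = True
    sg_window: int = 7
    sg_polyorder: int = 2
    # periodicity gate
    filter_alpha: float = 0.05
    filter_permutations: int = 999
    # phase assignment
    phase_boot: int = 999
    phase_alpha: float = 0.05
    phase_trim: float = 0.10
    phase_criterion: str = "window"
    # optional real inputs
    expression_path: str | None = None
    gmt_path: str | None = None

    def __post_init__(self) -> None:
        for name in ("filter_alpha", "phase_alpha"):
            v = getattr(self, name)
            if not 0.0 < v < 1.0:
                raise ValueError(f"{name} must lie in (0, 1)")
        for name in ("filter_permutations", "phase_boot"):
            if getattr(self, name) < 99:
                raise ValueError(f"{name} must be at least 99")
        if self.seed is None:
            raise ValueError("a seed is required for reproducible runs")

    @property
    def design(self) -> TimeDesign:
        return TimeDesign(self.period_h, self.interval_h, self.n_cycles)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        if "amp_range" in raw:
            raw["amp_range"] = tuple(raw["amp_range"])
        if "baseline_range" in raw:
            raw["baseline_range"] = tuple(raw["baseline_range"])
        if "planted" in raw:
            raw["planted"] = [tuple(p) for p in raw["planted"]]
        return cls(**raw)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["amp_range"] = list(d["amp_range"])
        d["baseline_range"] = list(d["baseline_range"])
        d["planted"] = [list(p) for p in d["planted"]]
        return d


def _write_stage(path: Path, writer) -> None:
    """Write through a .partial file, renaming into place on success."""
    partial = path.with_name(path.name + ".partial")
    writer(partial)
    os.replace(partial, path)


def run_all(config: RunConfig, outdir: str | Path) -> dict[str, Path]:
    """Run the whole pipeline, writing every intermediate artifact.

    Returns a mapping from artifact name to file path.  Any stage failure
    raises :class:`StageError` naming the stage; artifacts of completed
    stages remain, and the failing stage's partial output keeps a
    ``.partial`` suffix.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    design = config.design
    paths: dict[str, Path] = {}

    manifest = {
        "package": "circaphase",
        "version": __version__,
        "seed": config.seed,
        "config": config.to_dict(),
    }
    paths["manifest"] = outdir / "manifest.json"
    _write_stage(paths["manifest"], lambda p: p.write_text(json.dumps(manifest, indent=2)))

    stage = "simulate"
    try:
        if config.expression_path is None:
            matrix, truth = generate_expression(
                design=design,
                n_genes=config.n_genes,
                frac_oscillating=config.frac_oscillating,
                amp_range=config.amp_range,
                noise_sd=config.noise_sd,
                baseline_range=config.baseline_range,
                seed=config.seed,
                phase_on_grid=config.phase_on_grid,
            )
            annotation, enr_truth = generate_annotation(
                truth,
                design=design,
                n_terms=config.n_terms,
                genes_per_term=config.genes_per_term,
                planted=config.planted,
                seed=config.seed + 1,
            )
            paths["matrix"] = outdir / "matrix.tsv"
            _write_stage(paths["matrix"], lambda p: write_expression(matrix, p))
            paths["truth"] = outdir / "truth.tsv"
            _write_stage(
                paths["truth"],
                lambda p: truth.to_csv(p, sep="\t", index=False, float_format="%.12g"),
            )
            paths["gmt"] = outdir / "terms.gmt"
            _write_stage(paths["gmt"], lambda p: write_gmt(annotation, p))
            paths["enrichment_truth"] = outdir / "enrichment_truth.tsv"
            _write_stage(
                paths["enrichment_truth"],
                lambda p: enr_truth.to_csv(p, sep="\t", index=False, float_format="%.12g"),
            )
        else:
            stage = "ingest"
            matrix = read_expression(config.expression_path, design)
            if config.gmt_path is None:
                raise ValueError("gmt_path is required when expression_path is given")
            annotation = read_gmt(config.gmt_path, matrix.gene_ids)

        stage = "normalize"
        normalized, _ = normalize_matrix(
            matrix,
            smooth=config.smooth_reference,
            window=config.sg_window,
            polyorder=config.sg_polyorder,
        )
        paths["normalized"] = outdir / "normalized.tsv"
        _write_stage(paths["normalized"], lambda p: write_expression(normalized, p))

        stage = "filter"
        ptable = periodicity_table(
            normalized,
            alpha=config.filter_alpha,
            n_permutations=config.filter_permutations,
            random_state=config.seed + 2,
        )
        paths["periodicity"] = outdir / "periodicity.tsv"
        _write_stage(
            paths["periodicity"],
            lambda p: ptable.to_csv(p, sep="\t", index=False, float_format="%.12g"),
        )
        kept = ptable.loc[ptable["kept"], "gene_id"].tolist()
        paths["kept"] = outdir / "kept.txt"
        _write_stage(paths["kept"], lambda p: p.write_text("".join(g + "\n" for g in kept)))
        logger.info("filter: kept %d of %d genes", len(kept), normalized.n_genes)

        stage = "phase"
        oscillating = normalized.select(kept) if kept else None
        if oscillating is None:
            raise ValueError("no genes passed the periodicity gate")
        assignments = assign_matrix(
            oscillating,
            n_boot=config.phase_boot,
            trim=config.phase_trim,
            criterion=config.phase_criterion,
            random_state=config.seed + 3,
        )
        paths["assignments"] = outdir / "assignments.tsv"
        _write_stage(paths["assignments"], lambda p: write_assignments(assignments, p))

        stage = "enrich"
        groups = {p: set() for p in range(design.n_phases)}
        groups.update(select_confident(assignments, config.phase_alpha))
        table = phase_enrichment_table(groups, annotation, alpha=0.05)
        paths["enrichment"] = outdir / "enrichment.tsv"
        _write_stage(paths["enrichment"], lambda p: write_enrichment(table, p))
        paths["enrichment_wide"] = outdir / "enrichment_wide.tsv"
        wide = enrichment_wide(table)
        _write_stage(
            paths["enrichment_wide"],
            lambda p: wide.to_csv(p, sep="\t", float_format="%.4g"),
        )
        paths["abundance"] = outdir / "term_abundance.tsv"
        abundance = term_abundance_report(groups, annotation)
        _write_stage(
            paths["abundance"],
            lambda p: abundance.to_csv(p, sep="\t", index=False),
        )
    except Exception as exc:
        raise StageError(f"pipeline stage {stage!r} failed: {exc}") from exc

    return paths
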