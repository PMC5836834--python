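"""Readers and writers for expression tables, GMT annotation, and result tables.

Expression tables are delimited text (TSV/CSV), genes in rows, with a header
of zeitgeber labels (``ZT<number>``, case-insensitive, or bare numbers).
Columns are reordered to the design's time order when the labels permit it.
"""

from __future__ import annotations

import logging
import re
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .datatypes import (
    DesignMismatchError,
    ExpressionMatrix,
    ExpressionParseError,
    GeneSetAnnotation,
    GMTParseError,
    PhaseAssignment,
    TimeDesign,
)

logger = logging.getLogger(__name__)

_ZT_RE = re.compile(r"^\s*(?:zt)?\s*([+-]?\d+(?:\.\d+)?)\s*(?:h)?\s*$", re.IGNORECASE)

_FLOAT_FMT = "%.12g"


def _delimiter_for(path: str | Path) -> str:
    return "," if str(path).lower().endswith(".csv") else "\t"


def parse_zeitgeber_label(label: str) -> float | None:
    """Parse a column header into a zeitgeber hour, or None if unparseable."""
    m = _ZT_RE.match(str(label))
    return float(m.group(1)) if m else None


def read_expression(
    path: str | Path,
    design: TimeDesign,
    *,
    assume_design_order: bool = False,
) -> ExpressionMatrix:
    """Read a gene x sample expression table and align it to a design.

    The first column holds gene identifiers; remaining columns are samples.
    Headers of the form ``ZT<number>`` or bare numbers are mapped to the
    design's sample times and the columns reordered accordingly.  Headers
    that cannot be parsed require ``assume_design_order=True``, in which case
    columns are taken as already being in design time order.

    Raises
    ------
    DesignMismatchError
        Column count differs from the design, or the parsed times do not
        match the design's sample times.
    ExpressionParseError
        A non-numeric cell, duplicated gene id, or missing value.
    """
    sep = _delimiter_for(path)
    df = pd.read_csv(path, sep=sep, index_col=0, dtype=str)
    if df.shape[1] != design.n_samples:
        raise DesignMismatchError(
            f"{path}: {df.shape[1]} sample columns but the design defines "
            f"{design.n_samples}"
        )
    if df.index.has_duplicates:
        dup = df.index[df.index.duplicated()].unique().tolist()
        raise ExpressionParseError(f"{path}: duplicated gene ids {dup[:5]}")

    values = np.empty(df.shape, dtype=float)
    for j, col in enumerate(df.columns):
        raw = df[col]
        num = pd.to_numeric(raw, errors="coerce")
        bad = num.isna()
        if bad.any():
            i = int(np.argmax(bad.to_numpy()))
            cell = raw.iloc[i]
            kind = "missing value" if pd.isna(cell) else f"non-numeric value {cell!r}"
            raise ExpressionParseError(
                f"{path}: {kind} at row {df.index[i]!r}, column {col!r}"
            )
        values[:, j] = num.to_numpy()

    if assume_design_order:
        order = list(range(df.shape[1]))
    else:
        parsed = [parse_zeitgeber_label(c) for c in df.columns]
        if any(t is None for t in parsed):
            bad = [c for c, t in zip(df.columns, parsed) if t is None]
            raise ExpressionParseError(
                f"{path}: unparseable zeitgeber headers {bad[:5]}; pass "
                "assume_design_order=True if columns are already in design order"
            )
        wanted = list(design.sample_times)
        order = []
        remaining = list(enumerate(parsed))
        for t in wanted:
            hit = next((k for k, (_, pt) in enumerate(remaining) if abs(pt - t) < 1e-9), None)
            if hit is None:
                raise DesignMismatchError(
                    f"{path}: no column for zeitgeber time {t:g} h; "
                    f"headers parse to {sorted(p for _, p in enumerate(parsed))}"
                )
            order.append(remaining.pop(hit)[0])

    return ExpressionMatrix(list(df.index), values[:, order], design)


def write_expression(matrix: ExpressionMatrix, path: str | Path) -> None:
    sep = _delimiter_for(path)
    df = matrix.to_frame()
    df.index.name = "gene_id"
    df.to_csv(path, sep=sep, float_format=_FLOAT_FMT)


def read_gmt(path: str | Path, universe: Iterable[str]) -> GeneSetAnnotation:
    """Read a GMT annotation file, restricting gene sets to a universe.

    Each line is ``term_id <TAB> description <TAB> gene1 <TAB> gene2 ...``.
    Genes absent from the universe are dropped (count logged); terms whose
    sets become empty are removed.
    """
    universe = frozenset(str(g) for g in universe)
    terms: dict[str, tuple[str, frozenset]] = {}
    n_dropped = 0
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise GMTParseError(
                    f"{path}:{lineno}: expected at least 3 tab-separated fields, "
                    f"got {len(fields)}"
                )
            term_id, name = fields[0], fields[1]
            genes = {g for g in fields[2:] if g}
            kept = frozenset(genes & universe)
            n_dropped += len(genes) - len(kept)
            if kept:
                terms[term_id] = (name, kept)
    if n_dropped:
        logger.info("read_gmt: dropped %d gene ids outside the universe", n_dropped)
    return GeneSetAnnotation(terms=terms, universe=universe)


def write_gmt(annotation: GeneSetAnnotation, path: str | Path) -> None:
    with open(path, "w") as fh:
        for term_id in annotation.term_ids:
            name, genes = annotation.terms[term_id]
            fh.write("\t".join([term_id, name, *sorted(genes)]) + "\n")


ASSIGNMENT_COLUMNS = ["gene_id", "phase_index", "peak_zt", "correlation", "confidence_p"]


def write_assignments(assignments: Sequence[PhaseAssignment], path: str | Path) -> None:
    """Write phase calls as TSV, one row per gene, sorted by gene id."""
    rows = sorted(assignments, key=lambda a: a.gene_id)
    with open(path, "w") as fh:
        fh.write("\t".join(ASSIGNMENT_COLUMNS) + "\n")
        for a in rows:
            fh.write(
                "\t".join(
                    [
                        a.gene_id,
                        str(a.phase_index),
                        _FLOAT_FMT % a.peak_time_h,
                        _FLOAT_FMT % a.correlation,
                        _FLOAT_FMT % a.confidence_p,
                    ]
                )
                + "\n"
            )


def read_assignments(path: str | Path) -> list[PhaseAssignment]:
    df = pd.read_csv(path, sep="\t", dtype={"gene_id": str})
    missing = set(ASSIGNMENT_COLUMNS) - set(df.columns)
    if missing:
        raise ExpressionParseError(f"{path}: missing assignment columns {sorted(missing)}")
    return [
        PhaseAssignment(
            gene_id=str(r.gene_id),
            phase_index=int(r.phase_index),
            peak_time_h=float(r.peak_zt),
            correlation=float(r.correlation),
            confidence_p=float(r.confidence_p),
        )
        for r in df.itertuples()
    ]


def write_enrichment(table: pd.DataFrame, path: str | Path) -> None:
    """Write a long-format enrichment table deterministically ordered."""
    df = table.sort_values(["term_id", "phase_index"]).reset_index(drop=True)
    df.to_csv(path, sep="\t", index=False, float_format=_FLOAT_FMT)


def read_enrichment(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", dtype={"term_id": str, "term_name": str})
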