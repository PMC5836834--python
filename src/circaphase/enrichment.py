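"""Hypergeometric over-representation of annotation terms in phase groups.

For each (term, phase-group) pair the p-value is the upper tail
``P(X >= k)`` of a hypergeometric draw: ``n`` group genes sampled without
replacement from a universe of ``N`` background genes of which ``K`` carry
the term, observing ``k`` carriers in the group.  The whole background
(every gene on the array) is the universe.  A Benjamini-Hochberg column is
provided for reference only — the terms tested within a phase row are
heavily dependent, so the uncorrected p-values drive the default
highlighting.
"""

from __future__ import annotations

import logging
from typing import Mapping

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .datatypes import GeneSetAnnotation

logger = logging.getLogger(__name__)


def hypergeom_upper(k: int, K: int, n: int, N: int) -> float:
    """Upper-tail hypergeometric probability ``P(X >= k)``.

    Parameters: ``k`` observed carriers in the group, ``K`` carriers in the
    universe, ``n`` group size, ``N`` universe size.
    """
    if not (0 <= k <= min(K, n) and k <= K <= N and 0 <= n <= N):
        raise ValueError(
            f"invalid hypergeometric configuration k={k}, K={K}, n={n}, N={N}"
        )
    if k == 0:
        return 1.0
    # sf(k-1) = P(X >= k); scipy sums the tail stably in log space
    p = float(stats.hypergeom.sf(k - 1, N, K, n))
    return min(max(p, np.nextafter(0, 1)), 1.0)


def phase_enrichment_table(
    groups: Mapping[int, set],
    annotation: GeneSetAnnotation,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Long-format term x phase enrichment table.

    One row per (term, phase) with counts, the hypergeometric upper-tail
    ``p_value``, a per-term Benjamini-Hochberg ``bh_q`` across phases
    (reference only), and a ``significant`` flag at ``p <= alpha`` mirroring
    highlighted table cells.  Group genes outside the annotation universe
    are dropped with a logged count.
    """
    N = len(annotation.universe)
    clean_groups: dict[int, set] = {}
    n_outside = 0
    for phase, genes in groups.items():
        genes = {str(g) for g in genes}
        kept = genes & annotation.universe
        n_outside += len(genes) - len(kept)
        clean_groups[int(phase)] = kept
    if n_outside:
        logger.warning(
            "phase_enrichment_table: dropped %d group genes outside the universe",
            n_outside,
        )
    phases = sorted(clean_groups)
    rows = []
    for term_id in annotation.term_ids:
        term_genes = annotation.genes_of(term_id)
        for phase in phases:
            group = clean_groups[phase]
            k = len(group & term_genes)
            rows.append(
                {
                    "term_id": term_id,
                    "term_name": annotation.name_of(term_id),
                    "phase_index": phase,
                    "k": k,
                    "K": len(term_genes),
                    "n": len(group),
                    "N": N,
                    "p_value": hypergeom_upper(k, len(term_genes), len(group), N),
                }
            )
    df = pd.DataFrame(rows)
    if df.empty:
        return df.reindex(
            columns=[
                "term_id", "term_name", "phase_index",
                "k", "K", "n", "N", "p_value", "bh_q", "significant",
            ]
        )
    df["bh_q"] = (
        df.groupby("term_id", group_keys=False)["p_value"]
        .transform(lambda p: multipletests(p.to_numpy(), method="fdr_bh")[1])
    )
    df["significant"] = df["p_value"] <= alpha
    return df


def enrichment_wide(table: pd.DataFrame) -> pd.DataFrame:
    """Term x phase p-value matrix with a trailing per-phase gene-count row.

    The last row, labelled ``"Number of genes"``, holds each phase group's
    size (genes inside the universe), mirroring the layout of published
    phase-enrichment tables.
    """
    if table.empty:
        return pd.DataFrame()
    wide = table.pivot(index="term_id", columns="phase_index", values="p_value")
    wide = wide.sort_index()
    counts = table.drop_duplicates("phase_index").set_index("phase_index")["n"]
    wide.loc["Number of genes"] = counts.reindex(wide.columns).astype(float)
    return wide


def term_abundance_report(
    groups: Mapping[int, set],
    annotation: GeneSetAnnotation,
    top_m: int = 10,
) -> pd.DataFrame:
    """Most prevalent terms per phase group.

    For each phase, the ``top_m`` terms ranked by the number of group genes
    they annotate (descending; ties broken by term id, lexicographic).
    """
    rows = []
    for phase in sorted(groups):
        group = {str(g) for g in groups[phase]}
        counts = []
        for term_id in annotation.term_ids:
            c = len(group & annotation.genes_of(term_id))
            if c > 0:
                counts.append((term_id, c))
        counts.sort(key=lambda tc: (-tc[1], tc[0]))
        for rank, (term_id, c) in enumerate(counts[:top_m], start=1):
            rows.append(
                {
                    "phase_index": phase,
                    "rank": rank,
                    "term_id": term_id,
                    "term_name": annotation.name_of(term_id),
                    "count": c,
                }
            )
    return pd.DataFrame(rows, columns=["phase_index", "rank", "term_id", "term_name", "count"])
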