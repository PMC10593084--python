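"""Cohort-level summary tables of classified events."""

from __future__ import annotations

from typing import Sequence

import numpy as np
import pandas as pd

__all__ = ["events_table", "summarize", "SIZE_BIN_EDGES", "GENE_COUNT_BIN_EDGES"]

# Powers-of-ten size bins from 1 kb to 10 Mb with open tails.
SIZE_BIN_EDGES = [0, 1_000, 10_000, 100_000, 1_000_000, 10_000_000, np.inf]
SIZE_BIN_LABELS = ["<1kb", "1-10kb", "10-100kb", "100kb-1Mb", "1-10Mb", ">10Mb"]

# Gene-count bins matching the dosage-scoring cutoffs.
GENE_COUNT_BIN_EDGES = [0, 25, 35, 50, np.inf]
GENE_COUNT_BIN_LABELS = ["0-24", "25-34", "35-49", ">=50"]


def events_table(classified: Sequence) -> pd.DataFrame:
    """Flatten classified events into one row per event."""
    rows = []
    for ce in classified:
        e = ce.event
        span = e.span
        rows.append(
            {
                "event_id": e.event_id,
                "sample_id": e.sample_id,
                "chrom": span.chrom,
                "start_1based": span.start + 1,
                "end": span.end,
                "size_bp": span.length,
                "resolved_type": e.resolved_type.value,
                "n_components": len(e.components),
                "n_exons": e.n_exons,
                "n_genes_scoring": ce.gene_content.count_for_scoring(),
                "discordant_sources": ce.gene_content.discordant_sources,
                "disease_genes": ",".join(ce.gene_content.disease_genes),
                "panel_max_af": ce.panel_max_af,
                "cma_probes": None if ce.cma is None else ce.cma.n_probes,
                "cma_detectable": None if ce.cma is None else ce.cma.detectable,
                "high_confidence": ce.high_confidence,
                "total_points": ce.result.total,
                "classification": ce.result.classification.value,
            }
        )
    return pd.DataFrame(rows)


def summarize(df: pd.DataFrame) -> dict[str, pd.DataFrame]:
    """Count tables by size bin, type, gene-count bin and classification.

    Every table's grand total equals the number of events (conservation).
    """
    if len(df) == 0:
        empty = pd.DataFrame()
        return {k: empty for k in ("size_by_class", "type_by_class", "genes_by_class")}
    d = df.copy()
    d["size_bin"] = pd.cut(
        d["size_bp"], bins=SIZE_BIN_EDGES, labels=SIZE_BIN_LABELS, right=False
    )
    d["gene_bin"] = pd.cut(
        d["n_genes_scoring"],
        bins=GENE_COUNT_BIN_EDGES,
        labels=GENE_COUNT_BIN_LABELS,
        right=False,
    )
    return {
        "size_by_class": pd.crosstab(d["size_bin"], d["classification"], dropna=False),
        "type_by_class": pd.crosstab(d["resolved_type"], d["classification"]),
        "genes_by_class": pd.crosstab(d["gene_bin"], d["classification"], dropna=False),
    }
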