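"""Single-cell quality-control filters and the marker-co-expression doublet rule.

Cells are kept when their detected-gene count lies in [``min_genes``,
``max_genes``] and their mitochondrial count fraction is at most
``max_mito_fraction`` — removal applies strictly to cells *below/above* the
gene bounds and strictly *above* the mito bound, so boundary cells (exactly
200 genes, exactly 15% mitochondrial) survive.

A cell is called a doublet when markers from two or more distinct cell
lineages are both detected. Pan-immune markers (PTPRC) are excluded from
that rule: essentially every immune cell co-expresses them with its lineage
markers, so they carry no doublet signal.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io import ExpressionMatrix

DEFAULT_LINEAGE_MARKERS = {
    "epithelial": ("SFTPC", "SCGB3A1"),
    "T": ("CD3D",),
    "B_plasma": ("CD79A", "JCHAIN", "MZB1"),
    "myeloid": ("MARCO", "CD163"),
}
DEFAULT_PAN_IMMUNE = ("PTPRC",)


@dataclass
class QCThresholds:
    """Filter thresholds; defaults follow the standard 200/6500 gene and 15%
    mitochondrial cutoffs for droplet scRNA-seq."""

    min_genes: int = 200
    max_genes: int = 6500
    max_mito_fraction: float = 0.15
    lineage_marker_sets: dict = field(default_factory=lambda: dict(DEFAULT_LINEAGE_MARKERS))
    pan_immune_markers: tuple = DEFAULT_PAN_IMMUNE
    detection_threshold: float = 0.0  # a marker is "expressed" when count > this

    def __post_init__(self):
        if not self.min_genes < self.max_genes:
            raise ValueError("min_genes must be < max_genes")
        if not 0.0 <= self.max_mito_fraction <= 1.0:
            raise ValueError("max_mito_fraction must lie in [0, 1]")


#: removal reasons in priority order (a cell violating several rules is
#: reported once, under the first that applies)
REASON_PRIORITY = ("low_genes", "high_genes", "high_mito")


def qc_filter(expr: ExpressionMatrix, thresholds: QCThresholds | None = None):
    """Apply the gene-count and mitochondrial filters.

    Returns ``(filtered ExpressionMatrix, report)`` where ``report`` is a
    DataFrame indexed by removed cell id with boolean columns per reason and
    a ``primary_reason`` column. If no gene carries a mitochondrial flag the
    mito criterion is skipped with a warning rather than silently passing.
    """
    th = thresholds or QCThresholds()
    detected = expr.genes_detected()
    low = detected < th.min_genes
    high = detected > th.max_genes
    if expr.adata.var["mito"].any():
        mito = expr.mito_fraction() > th.max_mito_fraction
    else:
        warnings.warn("no mitochondrial genes flagged; mito criterion skipped")
        mito = pd.Series(False, index=expr.cell_ids)
    remove = low | high | mito
    report = pd.DataFrame(
        {"low_genes": low[remove], "high_genes": high[remove], "high_mito": mito[remove]}
    )
    primary = pd.Series("", index=report.index, dtype=object)
    for reason in reversed(REASON_PRIORITY):
        primary[report[reason]] = reason
    report["primary_reason"] = primary
    kept = ExpressionMatrix(expr.adata[~remove.to_numpy()].copy())
    return kept, report


def flag_marker_doublets(expr: ExpressionMatrix, thresholds: QCThresholds | None = None) -> set:
    """Return ids of cells expressing markers from >= 2 distinct lineages.

    Marker genes absent from the matrix shrink the corresponding lineage set
    and are reported in a warning; pan-immune markers never count.
    """
    th = thresholds or QCThresholds()
    counts = expr.counts()
    gene_pos = {g: i for i, g in enumerate(expr.gene_ids)}
    missing = []
    lineage_hit = {}
    for lineage, markers in th.lineage_marker_sets.items():
        cols = [gene_pos[g] for g in markers if g in gene_pos]
        missing += [g for g in markers if g not in gene_pos]
        if not cols:
            continue
        lineage_hit[lineage] = (counts[:, cols] > th.detection_threshold).any(axis=1)
    if missing:
        warnings.warn(f"lineage marker genes absent from matrix: {sorted(set(missing))}")
    if len(lineage_hit) < 2:
        return set()
    n_lineages = np.sum(np.column_stack(list(lineage_hit.values())), axis=1)
    return set(expr.cell_ids[n_lineages >= 2])
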