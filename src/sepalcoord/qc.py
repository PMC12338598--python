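"""Cell-level quality control and the per-cell transcript-fraction primitive.

The core statistic of the whole pipeline is the percentage of a cell's
transcripts that originate from a given gene set (computed on raw counts;
no normalization). QC filters retain cells with a detected-gene count
strictly between ``min_genes`` and ``max_genes`` and organelle transcript
fractions strictly below the mitochondrial and chloroplast caps — all four
inequalities are strict.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable

import numpy as np

from .io import CountMatrix

logger = logging.getLogger("sepalcoord")


@dataclass
class QcThresholds:
    """Cell-filter thresholds.

    ``min_genes``/``max_genes`` bound the detected-gene count (genes with
    count > 0); ``max_mito_pct``/``max_chloro_pct`` cap the organelle
    transcript percentages. Defaults follow standard practice for
    protoplast-derived floral tissue.
    """

    min_genes: int = 600
    max_genes: int = 6000
    max_mito_pct: float = 10.0
    max_chloro_pct: float = 20.0

    def __post_init__(self) -> None:
        if not self.min_genes < self.max_genes:
            raise ValueError("min_genes must be < max_genes")
        for pct in (self.max_mito_pct, self.max_chloro_pct):
            if not 0 <= pct <= 100:
                raise ValueError("percentage thresholds must lie in [0, 100]")


def compute_fraction(cell_counts: np.ndarray, set_mask: np.ndarray,
                     barcode: str = "<cell>") -> float:
    """Percentage of one cell's transcripts that come from the flagged genes.

    Parameters
    ----------
    cell_counts
        Per-gene raw counts for a single cell.
    set_mask
        Boolean mask (or integer index array) selecting the gene set's rows.
    """
    cell_counts = np.asarray(cell_counts, dtype=float).ravel()
    total = cell_counts.sum()
    if total <= 0:
        raise ValueError(f"cell {barcode} has zero total transcripts")
    return float(100.0 * cell_counts[set_mask].sum() / total)


def set_fractions(matrix: CountMatrix, gene_set: Iterable[str] | np.ndarray,
                  warn: bool = True) -> np.ndarray:
    """Vectorized :func:`compute_fraction` over every cell of a matrix.

    ``gene_set`` may be gene ids (resolved against the matrix; unknown ids
    ignored with a warning) or an integer row-index array.
    """
    gene_set = np.asarray(list(gene_set) if not isinstance(gene_set, np.ndarray) else gene_set)
    if gene_set.dtype.kind in "iu":
        idx = gene_set
    else:
        idx = matrix.gene_indices(gene_set, warn=warn)
    totals = matrix.total_counts().astype(float)
    zero = totals <= 0
    if zero.any():
        raise ValueError(
            f"cell {matrix.cell_ids[np.flatnonzero(zero)[0]]} has zero total transcripts"
        )
    if len(idx) == 0:
        return np.zeros(matrix.n_cells)
    subset = np.asarray(matrix.counts[idx, :].sum(axis=0)).ravel()
    return 100.0 * subset / totals


def organelle_fractions(matrix: CountMatrix) -> tuple[np.ndarray, np.ndarray]:
    """Per-cell mitochondrial and chloroplast transcript percentages."""
    mito = set_fractions(matrix, np.flatnonzero(matrix.gene_flags["mito"].to_numpy()))
    chloro = set_fractions(matrix, np.flatnonzero(matrix.gene_flags["chloro"].to_numpy()))
    return mito, chloro


def filter_cells(matrix: CountMatrix, thresholds: QcThresholds | None = None
                 ) -> tuple[list[str], dict[str, int]]:
    """Apply the cell filters; return retained barcodes and per-rule removal counts.

    A cell is retained when detected genes > min_genes AND detected genes
    < max_genes AND mito% < max_mito_pct AND chloro% < max_chloro_pct
    (all strict). Removal counts attribute each rule independently, so one
    cell can count against several rules.
    """
    thr = thresholds or QcThresholds()
    detected = matrix.detected_genes_per_cell()
    mito, chloro = organelle_fractions(matrix)
    pass_low = detected > thr.min_genes
    pass_high = detected < thr.max_genes
    pass_mito = mito < thr.max_mito_pct
    pass_chloro = chloro < thr.max_chloro_pct
    keep = pass_low & pass_high & pass_mito & pass_chloro
    removals = {
        "too_few_genes": int((~pass_low).sum()),
        "too_many_genes": int((~pass_high).sum()),
        "high_mito": int((~pass_mito).sum()),
        "high_chloro": int((~pass_chloro).sum()),
    }
    retained = [str(b) for b in matrix.cell_ids[keep]]
    if not retained:
        logger.warning("all %d cells removed by QC filters", matrix.n_cells)
    else:
        logger.info("QC retained %d / %d cells", len(retained), matrix.n_cells)
    return retained, removals


def protoplast_artifact_genes(sc_detected: Iterable[str],
                              bulk_expressed: Iterable[str]) -> set[str]:
    """Genes detected in the single-cell data but absent from a bulk reference.

    These are candidate protoplasting-induced artifacts: the dissociation
    itself switches them on, so they carry no biology of the intact tissue.
    """
    sc_detected = set(sc_detected)
    bulk_expressed = set(bulk_expressed)
    if sc_detected is None or bulk_expressed is None:  # pragma: no cover
        raise ValueError("both gene sets are required")
    return sc_detected - bulk_expressed


def detected_genes(matrix: CountMatrix, min_cells: int = 1) -> set[str]:
    """Genes with count > 0 in at least ``min_cells`` cells."""
    n_cells_per_gene = np.asarray((matrix.counts > 0).sum(axis=1)).ravel()
    return {str(g) for g in matrix.gene_ids[n_cells_per_gene >= min_cells]}
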