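"""Cell-cycle phase scoring and phase-variance gene filtering.

Proliferating meristem tissue clusters by cell-cycle phase unless the phase
signal is removed. The approach here scores each cell against S-phase and
G2/M gene lists with a binned control-gene module score, calls a phase per
cell, then deletes every gene whose log-normalized expression has more than
a threshold fraction (default 3%) of its variance explained by phase in a
one-way ANOVA, along with all mitochondrial genes.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .io import CountMatrix

logger = logging.getLogger("sepalcoord")

PHASES = ("G1", "S", "G2M")

#: Module-score defaults: 24 equal-frequency expression bins, 100 control
#: genes drawn per target gene.
DEFAULT_N_BINS = 24
DEFAULT_N_CTRL = 100


def log_normalize(matrix: CountMatrix, scale: float = 1e4) -> np.ndarray:
    """Natural log of (1 + counts-per-``scale``), dense genes x cells array."""
    totals = matrix.total_counts().astype(float)
    if (totals <= 0).any():
        raise ValueError("cells with zero total counts cannot be log-normalized")
    dense = np.asarray(matrix.counts.todense(), dtype=float)
    return np.log1p(scale * dense / totals[None, :])


def module_score(
    log_expr: np.ndarray,
    gene_ids: Sequence[str],
    target_set: Sequence[str],
    n_bins: int = DEFAULT_N_BINS,
    n_ctrl: int = DEFAULT_N_CTRL,
    seed: int = 0,
) -> np.ndarray:
    """Binned control-gene module score, one value per cell.

    Genes are placed into ``n_bins`` equal-frequency bins by their mean
    log-normalized expression across cells. For each target gene, ``n_ctrl``
    control genes are drawn uniformly from its bin (excluding all target
    genes; with replacement when the bin pool is smaller than ``n_ctrl``).
    The score is the mean expression of the target genes minus the mean
    expression of all drawn controls, per cell.
    """
    log_expr = np.asarray(log_expr, dtype=float)
    gene_ids = np.asarray(gene_ids, dtype=object)
    id_to_row = {g: i for i, g in enumerate(gene_ids)}
    target_rows = np.asarray(
        sorted({id_to_row[g] for g in target_set if g in id_to_row}), dtype=int
    )
    if target_rows.size == 0:
        raise ValueError("target_set resolves to zero genes in the matrix")
    n_genes = log_expr.shape[0]
    mean_expr = log_expr.mean(axis=1)
    # equal-frequency bins over the rank of the mean expression
    order = np.argsort(mean_expr, kind="stable")
    bins = np.empty(n_genes, dtype=int)
    bins[order] = np.floor(np.arange(n_genes) * n_bins / n_genes).astype(int)

    rng = np.random.default_rng(seed)
    target_mask = np.zeros(n_genes, dtype=bool)
    target_mask[target_rows] = True
    ctrl_rows: list[np.ndarray] = []
    for row in target_rows:
        pool = np.flatnonzero((bins == bins[row]) & ~target_mask)
        if pool.size == 0:
            logger.warning("no control genes available in bin of gene %s", gene_ids[row])
            continue
        replace = pool.size < n_ctrl
        ctrl_rows.append(rng.choice(pool, size=n_ctrl, replace=replace))
    if not ctrl_rows:
        raise ValueError("no control genes could be drawn for any target gene")
    controls = np.concatenate(ctrl_rows)
    return log_expr[target_rows, :].mean(axis=0) - log_expr[controls, :].mean(axis=0)


def assign_phase(s_score: float, g2m_score: float) -> str:
    """Phase call: G1 when neither score is positive, otherwise the larger
    score's phase; a positive tie goes to S."""
    if s_score <= 0 and g2m_score <= 0:
        return "G1"
    if s_score >= g2m_score:
        return "S"
    return "G2M"


@dataclass
class PhaseScores:
    """Per-cell S and G2/M module scores and the resulting phase calls."""

    table: pd.DataFrame  # columns: s_score, g2m_score, phase; index: barcode

    @property
    def phases(self) -> pd.Series:
        return self.table["phase"]


def score_phases(
    matrix: CountMatrix,
    s_genes: Sequence[str],
    g2m_genes: Sequence[str],
    n_bins: int = DEFAULT_N_BINS,
    n_ctrl: int = DEFAULT_N_CTRL,
    seed: int = 0,
) -> PhaseScores:
    """Score both phase gene lists and call a phase for every cell."""
    log_expr = log_normalize(matrix)
    s = module_score(log_expr, matrix.gene_ids, s_genes, n_bins, n_ctrl, seed=seed)
    g2m = module_score(log_expr, matrix.gene_ids, g2m_genes, n_bins, n_ctrl, seed=seed + 1)
    phase = [assign_phase(a, b) for a, b in zip(s, g2m)]
    table = pd.DataFrame(
        {"s_score": s, "g2m_score": g2m, "phase": phase}, index=matrix.cell_ids
    )
    return PhaseScores(table)


def variance_explained(gene_values: np.ndarray, phase_labels: Sequence[str]) -> float:
    """One-way ANOVA R^2 of one gene's values on the phase labels.

    R^2 = SS_between / SS_total; returns 0 when the gene is constant.
    """
    values = np.asarray(gene_values, dtype=float).ravel()
    labels = np.asarray(phase_labels)
    if values.size < 3:
        raise ValueError("need at least 3 cells")
    if len(np.unique(labels)) < 2:
        raise ValueError("need at least 2 distinct phase labels")
    grand = values.mean()
    ss_total = float(((values - grand) ** 2).sum())
    if ss_total == 0:
        return 0.0
    ss_between = 0.0
    for lab in np.unique(labels):
        grp = values[labels == lab]
        ss_between += grp.size * (grp.mean() - grand) ** 2
    return float(ss_between / ss_total)


def variance_explained_all(log_expr: np.ndarray, phase_labels: Sequence[str]) -> np.ndarray:
    """Vectorized one-way ANOVA R^2 for every gene (row) at once."""
    X = np.asarray(log_expr, dtype=float)
    labels = np.asarray(phase_labels)
    if X.shape[1] < 3:
        raise ValueError("need at least 3 cells")
    uniq = np.unique(labels)
    if uniq.size < 2:
        raise ValueError("need at least 2 distinct phase labels")
    grand = X.mean(axis=1, keepdims=True)
    ss_total = ((X - grand) ** 2).sum(axis=1)
    ss_between = np.zeros(X.shape[0])
    for lab in uniq:
        cols = labels == lab
        n = cols.sum()
        ss_between += n * (X[:, cols].mean(axis=1) - grand.ravel()) ** 2
    with np.errstate(invalid="ignore", divide="ignore"):
        r2 = np.where(ss_total > 0, ss_between / ss_total, 0.0)
    return np.clip(r2, 0.0, 1.0)


def remove_cc_genes(
    matrix: CountMatrix,
    phase_labels: Sequence[str],
    threshold: float = 0.03,
) -> tuple[CountMatrix, pd.DataFrame]:
    """Drop genes with phase-ANOVA R^2 strictly above ``threshold`` and all
    mitochondrial genes; return the reduced matrix and a per-gene report.

    The report lists every gene's r_squared, whether it was removed, and the
    reason (``cell_cycle``, ``mitochondrial``, or empty).
    """
    log_expr = log_normalize(matrix)
    r2 = variance_explained_all(log_expr, phase_labels)
    mito = matrix.gene_flags["mito"].to_numpy()
    cc_hit = r2 > threshold
    removed = cc_hit | mito
    reason = np.where(mito, "mitochondrial", np.where(cc_hit, "cell_cycle", ""))
    report = pd.DataFrame(
        {"gene_id": matrix.gene_ids, "r_squared": r2, "removed": removed, "reason": reason}
    )
    logger.info(
        "cell-cycle filter removed %d genes (%d by R^2 > %g, %d mitochondrial)",
        int(removed.sum()), int((cc_hit & ~mito).sum()), threshold, int(mito.sum()),
    )
    return matrix.subset_genes(~removed), report


def read_cc_gene_list(path: str | Path) -> tuple[list[str], list[str]]:
    """Read a two-column TSV (gene id, phase in {S, G2M}); return (S, G2M) lists."""
    df = pd.read_csv(path, sep="\t", header=None, comment="#", dtype=str)
    s = df.loc[df[1].str.upper() == "S", 0].tolist()
    g2m = df.loc[df[1].str.upper() == "G2M", 0].tolist()
    return s, g2m
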