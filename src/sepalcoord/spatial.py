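"""Spot-level analyses for spatial transcriptomics capture areas.

Each capture spot aggregates transcripts from several cells; a reference-
based deconvolution (performed upstream, consumed here as a spots x
clusters prediction-score matrix) assigns each spot the cell cluster with
the highest score. Downstream the module summarizes per-genotype cluster
proportions (omitting clusters mapped by fewer than ``min_spots`` spots in
either genotype, while keeping those spots in the denominators), applies a
capture-area mitochondrial QC, and runs the same per-spot gene-set
fraction/contrast machinery as the single-cell side with best-cluster
labels as groups.
"""

from __future__ import annotations

import logging
from typing import Sequence

import numpy as np
import pandas as pd

from .io import CountMatrix, GeneSetCollection
from .hormone import contrast_clusters, score_cells
from .qc import set_fractions

logger = logging.getLogger("sepalcoord")

UNASSIGNED = "unassigned"


def best_cluster(scores: pd.DataFrame) -> pd.Series:
    """Per-spot argmax cluster of a spots x clusters prediction-score matrix.

    Ties go to the lowest cluster label in sort order (logged); a spot whose
    scores are all zero is labeled ``unassigned``.
    """
    values = scores.to_numpy(dtype=float)
    if not np.isfinite(values).all():
        raise ValueError("prediction scores must be finite")
    if (values < 0).any():
        raise ValueError("prediction scores must be non-negative")
    cols = np.asarray(scores.columns, dtype=object)
    order = np.argsort([str(c) for c in cols], kind="stable")
    ordered = values[:, order]
    best = cols[order][np.argmax(ordered, axis=1)]
    ties = (ordered == ordered.max(axis=1, keepdims=True)).sum(axis=1) > 1
    if ties.any():
        logger.info("%d spots had tied prediction scores; lowest label kept", int(ties.sum()))
    labels = pd.Series(best, index=scores.index, name="best_cluster")
    labels[values.max(axis=1) == 0] = UNASSIGNED
    return labels


def cluster_spot_proportions(
    labels: Sequence,
    genotype: Sequence,
    min_spots: int = 10,
) -> pd.DataFrame:
    """Per-genotype fraction of spots best-mapped to each cluster.

    Fractions are computed over *all* spots of a genotype; clusters with
    fewer than ``min_spots`` spots in either genotype are omitted from the
    output table but their spots still count in the denominators.
    """
    df = pd.DataFrame({"cluster": list(labels), "genotype": list(genotype)})
    genotypes = sorted(df["genotype"].unique(), key=str)
    if len(genotypes) < 2:
        raise ValueError("two genotypes required for proportion comparison")
    counts = df.groupby(["cluster", "genotype"], sort=True).size().unstack(fill_value=0)
    counts = counts.reindex(columns=genotypes, fill_value=0)
    totals = df["genotype"].value_counts().reindex(genotypes)
    props = counts / totals
    keep = (counts >= min_spots).all(axis=1)
    omitted = counts.index[~keep].tolist()
    if omitted:
        logger.info("omitting clusters mapped by <%d spots in a genotype: %s",
                    min_spots, omitted)
    out = props.loc[keep].copy()
    out.columns = [f"proportion_{g}" for g in genotypes]
    for g in genotypes:
        out[f"n_spots_{g}"] = counts.loc[keep, g]
    return out.reset_index()


def spot_qc(
    matrix: CountMatrix,
    capture_area: Sequence,
    area_flag_factor: float = 2.0,
) -> tuple[pd.DataFrame, list[str]]:
    """Capture-area QC on the median per-spot mitochondrial fraction.

    An area is flagged (candidate dying tissue) when its median spot mito
    percentage exceeds ``area_flag_factor`` times the median of the other
    areas' medians.
    """
    areas = pd.Series(list(capture_area), index=matrix.cell_ids).astype(str)
    if areas.nunique() < 2:
        raise ValueError("need at least 2 capture areas")
    mito_idx = np.flatnonzero(matrix.gene_flags["mito"].to_numpy())
    mito_pct = pd.Series(set_fractions(matrix, mito_idx), index=matrix.cell_ids)
    medians = mito_pct.groupby(areas).median()
    flagged = []
    for area, med in medians.items():
        others = medians.drop(area)
        if med > area_flag_factor * others.median():
            flagged.append(area)
    summary = medians.rename("median_mito_pct").reset_index().rename(
        columns={"index": "capture_area"}
    )
    summary.columns = ["capture_area", "median_mito_pct"]
    summary["flagged"] = summary["capture_area"].isin(flagged)
    if flagged:
        logger.warning("capture areas flagged for high mito fraction: %s", flagged)
    return summary, flagged


def score_spots(
    matrix: CountMatrix,
    sets: GeneSetCollection,
    best_labels: Sequence,
    genotype: Sequence,
    alpha: float = 0.05,
    reference: str | None = None,
    mutant: str | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-spot gene-set fractions plus genotype contrasts grouped by the
    best-mapping cluster (Bonferroni family = n_groups x n_sets)."""
    fractions = score_cells(matrix, sets)
    contrasts = contrast_clusters(
        fractions, best_labels, genotype, alpha=alpha,
        reference=reference, mutant=mutant,
    )
    return fractions, contrasts
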