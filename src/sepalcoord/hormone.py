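"""Hormone-response gene-set scoring and per-cluster genotype contrasts.

The signaling level of a hormone in a cell is read out from the percentage
of the cell's transcripts that come from genes up- (or down-) regulated by
exogenous application of that hormone: a higher up-set fraction together
with a lower down-set fraction indicates higher signaling. Per cluster, the
two genotypes are contrasted with a two-sided Wilcoxon rank-sum test over
cells; the family-wise error is controlled by a Bonferroni correction whose
family size (clusters x gene sets) is always derived from the inputs. A
17-cluster x 12-set analysis at alpha = 0.05 therefore tests each row at
p < 0.05/204 ~= 0.000245.

Dot-plot statistics follow the same convention throughout: dot size is
log10(1/p) and dot color is the mutant-minus-reference mean difference.
"""

from __future__ import annotations

import logging
import math
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .io import CountMatrix, GeneSetCollection
from .qc import set_fractions

logger = logging.getLogger("sepalcoord")

#: Nested star thresholds (before per-family division).
BASE_ALPHAS = (0.05, 0.01, 0.001, 0.0001)

#: Combined sample size at or below which the Wilcoxon null is enumerated
#: exactly (tie-free samples only).
EXACT_LIMIT = 20


def bonferroni_threshold(alpha: float, n_tests: int) -> float:
    """Per-test significance threshold alpha / n_tests."""
    if n_tests < 1:
        raise ValueError("n_tests must be >= 1")
    return alpha / n_tests


def score_cells(matrix: CountMatrix, sets: GeneSetCollection) -> pd.DataFrame:
    """Per-cell percentage of transcripts from each hormone gene set.

    Returns a frame indexed by barcode with one ``hormone_direction``
    column per set.
    """
    data = {s.key: set_fractions(matrix, s.genes) for s in sets}
    return pd.DataFrame(data, index=matrix.cell_ids)


def wilcoxon_rank_sum(x: Sequence[float], y: Sequence[float]) -> float:
    """Two-sided Wilcoxon rank-sum (Mann-Whitney) p-value.

    Uses exact null enumeration when the combined sample size is at most
    20 and there are no ties, otherwise the normal approximation with
    tie-corrected variance and continuity correction.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both samples must be non-empty")
    combined = np.concatenate([x, y])
    tie_free = np.unique(combined).size == combined.size
    method = "exact" if (combined.size <= EXACT_LIMIT and tie_free) else "asymptotic"
    res = stats.mannwhitneyu(x, y, alternative="two-sided", method=method)
    return float(min(res.pvalue, 1.0))


def dot_size(p: float) -> float:
    """log10 of the inverse p-value; 0 when p = 1."""
    return float(-math.log10(p)) if p > 0 else math.inf


def star_annotation(p: float, n_groups: int,
                    base_alphas: Sequence[float] = BASE_ALPHAS) -> int:
    """Number of nested Bonferroni-adjusted thresholds the p-value clears.

    With 17 groups the four default thresholds are 0.05/17 ~= 0.00294,
    0.01/17 ~= 0.00059, 0.001/17 ~= 0.000059, 0.0001/17 ~= 0.0000059.
    """
    if n_groups < 1:
        raise ValueError("n_groups must be >= 1")
    return int(sum(p < a / n_groups for a in base_alphas))


def _resolve_genotypes(genotypes: pd.Series, reference: str | None,
                       mutant: str | None) -> tuple[str, str]:
    uniq = sorted(map(str, pd.unique(genotypes)))
    if len(uniq) != 2:
        raise ValueError(f"exactly two genotype labels required, got {uniq}")
    if reference is None:
        wt_like = [g for g in uniq if g.upper() in ("WT", "WILDTYPE", "WILD_TYPE", "COL-0", "COL0")]
        reference = wt_like[0] if wt_like else uniq[0]
    if mutant is None:
        mutant = next(g for g in uniq if g != reference)
    if {reference, mutant} != set(uniq):
        raise ValueError("reference/mutant labels do not match the data")
    return reference, mutant


def contrast_clusters(
    scores: pd.DataFrame,
    cluster_labels: Sequence,
    genotype_labels: Sequence,
    alpha: float = 0.05,
    reference: str | None = None,
    mutant: str | None = None,
    set_info: Mapping[str, tuple[str, str]] | None = None,
) -> pd.DataFrame:
    """Genotype contrast of gene-set fractions within each cluster.

    For every (cluster, set) pair: per-genotype means, the mutant-minus-
    reference difference, the two-sided Wilcoxon rank-sum p over cells,
    dot_size = log10(1/p), a significance call at the Bonferroni threshold
    alpha / (n_clusters x n_sets), and a star count at the per-cluster
    family. Clusters with fewer than 2 cells in either genotype produce a
    row with p = 1 and a warning.

    Parameters
    ----------
    scores
        Cells x sets fraction table (from :func:`score_cells`); columns
        named ``hormone_direction``.
    cluster_labels, genotype_labels
        Per-cell labels aligned with ``scores`` rows.
    set_info
        Optional mapping column -> (hormone, direction); inferred from the
        column names when omitted.
    """
    clusters = pd.Series(list(cluster_labels), index=scores.index)
    genotypes = pd.Series(list(genotype_labels), index=scores.index).astype(str)
    reference, mutant = _resolve_genotypes(genotypes, reference, mutant)
    cluster_ids = sorted(pd.unique(clusters), key=str)
    set_cols = list(scores.columns)
    n_tests = len(cluster_ids) * len(set_cols)
    threshold = bonferroni_threshold(alpha, n_tests)

    rows = []
    for cl in cluster_ids:
        in_cl = clusters == cl
        ref_cells = in_cl & (genotypes == reference)
        mut_cells = in_cl & (genotypes == mutant)
        degenerate = ref_cells.sum() < 2 or mut_cells.sum() < 2
        if degenerate:
            logger.warning(
                "cluster %s has <2 cells in a genotype (%d ref, %d mut); p set to 1",
                cl, int(ref_cells.sum()), int(mut_cells.sum()),
            )
        for col in set_cols:
            if set_info and col in set_info:
                hormone, direction = set_info[col]
            else:
                hormone, _, direction = col.rpartition("_")
            ref_vals = scores.loc[ref_cells, col].to_numpy()
            mut_vals = scores.loc[mut_cells, col].to_numpy()
            mean_ref = float(ref_vals.mean()) if ref_vals.size else float("nan")
            mean_mut = float(mut_vals.mean()) if mut_vals.size else float("nan")
            p = 1.0 if degenerate else wilcoxon_rank_sum(mut_vals, ref_vals)
            rows.append(
                {
                    "cluster": cl,
                    "hormone": hormone,
                    "direction": direction,
                    "mean_ref": mean_ref,
                    "mean_mut": mean_mut,
                    "diff": mean_mut - mean_ref,
                    "p": p,
                    "dot_size": dot_size(p),
                    "significant": p < threshold,
                    "stars": star_annotation(p, len(cluster_ids)),
                }
            )
    table = pd.DataFrame(rows)
    table.attrs.update(
        {
            "alpha": alpha,
            "n_clusters": len(cluster_ids),
            "n_sets": len(set_cols),
            "n_tests": n_tests,
            "bonferroni_threshold": threshold,
            "star_family": len(cluster_ids),
            "reference": reference,
            "mutant": mutant,
        }
    )
    return table


def infer_direction(row_up: Mapping, row_down: Mapping) -> tuple[str, str | None]:
    """Directional signaling call from the up-set and down-set contrast rows.

    Higher hormone signaling in the mutant predicts the up-set fraction to
    rise and the down-set fraction to fall; evidence is a significant
    contrast with the matching sign on either set. Concordant evidence from
    both sets is a strong call, from one a weak call; conflicting or absent
    evidence is inconclusive.

    Returns ``(call, confidence)`` with call in {"higher_in_mutant",
    "lower_in_mutant", "inconclusive"} and confidence in
    {"strong", "weak", None}.
    """
    if (row_up["cluster"], row_up["hormone"]) != (row_down["cluster"], row_down["hormone"]):
        raise ValueError("rows refer to different (cluster, hormone) pairs")
    if row_up["direction"] != "up" or row_down["direction"] != "down":
        raise ValueError("expected one up-set row and one down-set row")
    up_hi = bool(row_up["significant"]) and row_up["diff"] > 0
    down_hi = bool(row_down["significant"]) and row_down["diff"] < 0
    up_lo = bool(row_up["significant"]) and row_up["diff"] < 0
    down_lo = bool(row_down["significant"]) and row_down["diff"] > 0
    higher = up_hi or down_hi
    lower = up_lo or down_lo
    if higher and not lower:
        return "higher_in_mutant", ("strong" if (up_hi and down_hi) else "weak")
    if lower and not higher:
        return "lower_in_mutant", ("strong" if (up_lo and down_lo) else "weak")
    return "inconclusive", None


def direction_calls(table: pd.DataFrame) -> pd.DataFrame:
    """Apply :func:`infer_direction` to every (cluster, hormone) pair of a
    contrast table that contains both an up and a down row."""
    rows = []
    for (cl, hormone), grp in table.groupby(["cluster", "hormone"], sort=True):
        ups = grp[grp["direction"] == "up"]
        downs = grp[grp["direction"] == "down"]
        if len(ups) != 1 or len(downs) != 1:
            continue
        call, conf = infer_direction(ups.iloc[0], downs.iloc[0])
        rows.append({"cluster": cl, "hormone": hormone, "call": call, "confidence": conf})
    return pd.DataFrame(rows)


def dot_plot(table: pd.DataFrame, path=None):
    """Dot plot of a contrast table: rows are gene sets, columns clusters,
    dot size log10(1/p), color the mutant-minus-reference difference.
    Non-significant rows are suppressed, as in the analysis convention."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    shown = table[table["significant"]].copy()
    sets = sorted((table["hormone"] + "_" + table["direction"]).unique())
    clusters = sorted(table["cluster"].unique(), key=str)
    fig, ax = plt.subplots(figsize=(1 + 0.45 * len(clusters), 1 + 0.4 * len(sets)))
    if not shown.empty:
        xs = [clusters.index(c) for c in shown["cluster"]]
        ys = [sets.index(h + "_" + d) for h, d in zip(shown["hormone"], shown["direction"])]
        sizes = np.clip(shown["dot_size"].replace(np.inf, 300.0), 0, 300)
        sc = ax.scatter(xs, ys, s=10 * sizes, c=shown["diff"], cmap="RdBu_r")
        fig.colorbar(sc, ax=ax, label="mutant - reference (% of transcripts)")
    ax.set_xticks(range(len(clusters)), [str(c) for c in clusters])
    ax.set_yticks(range(len(sets)), sets)
    ax.set_xlabel("cluster")
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=150)
        plt.close(fig)
    return fig
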