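"""Shared fixtures and independent oracles for the test suite."""

from __future__ import annotations

from itertools import combinations

import numpy as np
import pandas as pd
import pytest
import scipy.sparse as sp

from sepalcoord.io import CountMatrix, GeneSet, GeneSetCollection


# ---------------------------------------------------------------------------
# Independent oracles (deliberately brute-force; never share code with the
# implementations they check)
# ---------------------------------------------------------------------------

def wilcoxon_enumeration_p(x, y) -> float:
    """Two-sided rank-sum p by exhaustive enumeration of rank assignments.

    Valid for tie-free samples. Enumerates every C(n_x+n_y, n_x) split of
    the pooled ranks, computes the rank-sum statistic for each, and returns
    the fraction of splits whose statistic is at least as extreme (in
    distance from its mean) as the observed one.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    pooled = np.concatenate([x, y])
    assert len(np.unique(pooled)) == len(pooled), "oracle requires tie-free input"
    ranks = pd.Series(pooled).rank().to_numpy()
    nx = len(x)
    observed = ranks[:nx].sum()
    mean = nx * (len(pooled) + 1) / 2.0
    obs_dev = abs(observed - mean)
    count = 0
    total = 0
    for idx in combinations(range(len(pooled)), nx):
        stat = ranks[list(idx)].sum()
        if abs(stat - mean) >= obs_dev - 1e-9:
            count += 1
        total += 1
    return count / total


def anova_r2_bruteforce(values, labels) -> float:
    """One-way ANOVA R^2 computed from the residuals of the group-mean fit."""
    values = np.asarray(values, dtype=float)
    labels = np.asarray(labels)
    fitted = np.empty_like(values)
    for lab in np.unique(labels):
        mask = labels == lab
        fitted[mask] = values[mask].mean()
    ss_res = ((values - fitted) ** 2).sum()
    ss_tot = ((values - values.mean()) ** 2).sum()
    if ss_tot == 0:
        return 0.0
    return 1.0 - ss_res / ss_tot


@pytest.fixture(scope="session")
def wilcoxon_oracle():
    return wilcoxon_enumeration_p


@pytest.fixture(scope="session")
def anova_oracle():
    return anova_r2_bruteforce


# ---------------------------------------------------------------------------
# Small hand-built fixtures
# ---------------------------------------------------------------------------

def make_matrix(counts, gene_ids=None, cell_ids=None, mito=None, chloro=None,
                cell_meta=None) -> CountMatrix:
    counts = np.asarray(counts)
    n_genes, n_cells = counts.shape
    gene_ids = gene_ids or [f"G{i}" for i in range(n_genes)]
    cell_ids = cell_ids or [f"C{i}" for i in range(n_cells)]
    flags = pd.DataFrame(
        {
            "mito": mito if mito is not None else [False] * n_genes,
            "chloro": chloro if chloro is not None else [False] * n_genes,
        },
        index=gene_ids,
    )
    return CountMatrix(sp.csr_matrix(counts), np.asarray(gene_ids, dtype=object),
                       np.asarray(cell_ids, dtype=object), flags,
                       cell_meta if cell_meta is not None else pd.DataFrame(index=cell_ids))


@pytest.fixture
def tiny_matrix() -> CountMatrix:
    """4 genes x 3 cells with one mito and one chloro gene."""
    counts = np.array([
        [10, 0, 5],    # G0 (mito)
        [20, 50, 5],   # G1
        [30, 25, 60],  # G2
        [40, 25, 30],  # G3 (chloro)
    ])
    return make_matrix(counts, mito=[True, False, False, False],
                       chloro=[False, False, False, True])


@pytest.fixture
def two_set_collection() -> GeneSetCollection:
    return GeneSetCollection([
        GeneSet("brassinosteroid", "up", ("G1",)),
        GeneSet("brassinosteroid", "down", ("G2",)),
    ])
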