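"""Ratiometric reporter quantification (BES1/H2B per nucleus).

The per-nucleus ratio of a hormone-responsive nuclear signal (BES1 fusion)
to a constitutive nuclear signal (H2B fusion) proxies brassinosteroid
signaling level. Nuclei roll up to per-sepal summaries: the mean ratio
(signaling level) and its coefficient of variation (cell-to-cell
variability), which are then compared between groups with Wilcoxon
rank-sum tests, overall and stratified by sepal position.
"""

from __future__ import annotations

import logging
import math
from pathlib import Path

import numpy as np
import pandas as pd

from .hormone import wilcoxon_rank_sum

logger = logging.getLogger("sepalcoord")

NUCLEUS_COLUMNS = ["nucleus_id", "bud_id", "sepal_id", "position", "group",
                   "bes1_signal", "h2b_signal"]


def nucleus_ratio(bes1: float, h2b: float, nucleus_id: str = "<nucleus>") -> float:
    """BES1 signal divided by H2B signal for one nucleus."""
    if h2b <= 0:
        raise ValueError(f"nucleus {nucleus_id} has non-positive H2B signal")
    if bes1 < 0:
        raise ValueError(f"nucleus {nucleus_id} has negative BES1 signal")
    return bes1 / h2b


def read_nuclei(path: str | Path) -> pd.DataFrame:
    """Read a nucleus table CSV (header-matched; extra columns ignored)."""
    df = pd.read_csv(path, comment="#")
    missing = [c for c in ("sepal_id", "group", "bes1_signal", "h2b_signal")
               if c not in df.columns]
    if missing:
        raise ValueError(f"nuclei CSV missing required columns: {missing}")
    return df


def sepal_summary(records: pd.DataFrame, min_nuclei: int = 5) -> pd.DataFrame:
    """Per-sepal mean and CV of the nucleus BES1/H2B ratios.

    CV uses the sample (n-1) standard deviation. Sepals with fewer than
    ``min_nuclei`` nuclei are dropped with a warning; a sepal whose mean
    ratio is zero gets a missing CV.
    """
    df = records.copy()
    if (df["h2b_signal"] <= 0).any():
        bad = df.loc[df["h2b_signal"] <= 0].iloc[0]
        raise ValueError(f"nucleus {bad.get('nucleus_id', '<unknown>')} has "
                         "non-positive H2B signal")
    df["ratio"] = df["bes1_signal"] / df["h2b_signal"]
    keys = [c for c in ("sepal_id", "bud_id", "position", "group") if c in df.columns]
    rows = []
    dropped = 0
    for _, grp in df.groupby("sepal_id", sort=True):
        n = len(grp)
        if n < min_nuclei:
            dropped += 1
            continue
        mean = float(grp["ratio"].mean())
        sd = float(grp["ratio"].std(ddof=1))
        if mean == 0:
            logger.warning("sepal %s has zero mean ratio; CV undefined",
                           grp["sepal_id"].iloc[0])
            cv = math.nan
        else:
            cv = sd / mean
        row = {k: grp[k].iloc[0] for k in keys}
        row.update({"n_nuclei": n, "mean_ratio": mean, "cv_ratio": cv})
        rows.append(row)
    if dropped:
        logger.warning("dropped %d sepals with < %d nuclei", dropped, min_nuclei)
    return pd.DataFrame(rows)


def group_compare(summaries: pd.DataFrame, by: str = "overall") -> pd.DataFrame:
    """Wilcoxon rank-sum comparison of per-sepal metrics between two groups.

    ``by='overall'`` compares all sepals; ``by='position'`` additionally
    stratifies by sepal position. Both ``mean_ratio`` and ``cv_ratio`` are
    tested two-sided. Strata with fewer than 2 sepals in either group yield
    a row with a missing p and a warning.
    """
    if by not in ("overall", "position"):
        raise ValueError("by must be 'overall' or 'position'")
    groups = sorted(summaries["group"].astype(str).unique())
    if len(groups) != 2:
        raise ValueError(f"exactly two groups required, got {groups}")
    strata = [("overall", summaries)]
    if by == "position":
        strata += [(str(pos), grp) for pos, grp in summaries.groupby("position", sort=True)]
    rows = []
    for stratum, data in strata:
        a = data[data["group"].astype(str) == groups[0]]
        b = data[data["group"].astype(str) == groups[1]]
        for metric in ("mean_ratio", "cv_ratio"):
            x = a[metric].dropna().to_numpy()
            y = b[metric].dropna().to_numpy()
            if len(x) < 2 or len(y) < 2:
                logger.warning("stratum %s has <2 sepals in a group; p omitted", stratum)
                p = math.nan
            else:
                p = wilcoxon_rank_sum(x, y)
            rows.append({
                "stratum": stratum,
                "metric": metric,
                "group_a": groups[0],
                "group_b": groups[1],
                "n_a": len(x),
                "n_b": len(y),
                "median_a": float(np.median(x)) if len(x) else math.nan,
                "median_b": float(np.median(y)) if len(y) else math.nan,
                "p": p,
            })
    return pd.DataFrame(rows)
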