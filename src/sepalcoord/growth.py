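"""Sepal elongation and growth-coordination metrics.

A flower bud carries one outer, one or two inner, and two lateral sepals
that must elongate coordinately to close the bud. Two families of metrics
quantify the coordination:

* single-timepoint length ratios (outer/inner, outer/bud, inner/bud) from
  measured sepal and bud lengths;
* time-series area metrics from lineage-tracked segmentations: absolute
  growth per interval, each sepal's fractional contribution to the bud's
  total growth, and outer/inner (and outer/lateral) area ratios, where two
  inner sepals are merged into one before the outer/inner ratio so a split
  inner does not inflate it.
"""

from __future__ import annotations

import logging
import math
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger("sepalcoord")

POSITIONS = ("outer", "inner", "lateral")

#: Display range applied to per-cell growth-ratio heat values.
CELL_RATIO_DISPLAY_RANGE = (0.0, 2.5)


def length_ratios(outer_length: float | None, inner_length: float | None,
                  bud_length: float | None) -> dict[str, float]:
    """Elementwise length ratios; a missing operand gives a missing ratio."""
    def _ratio(a, b):
        if a is None or b is None or (isinstance(a, float) and math.isnan(a)) \
                or (isinstance(b, float) and math.isnan(b)):
            return math.nan
        if a <= 0 or b <= 0:
            raise ValueError("lengths must be positive when present")
        return a / b

    return {
        "outer_over_inner": _ratio(outer_length, inner_length),
        "outer_over_bud": _ratio(outer_length, bud_length),
        "inner_over_bud": _ratio(inner_length, bud_length),
    }


def length_ratio_table(lengths: pd.DataFrame) -> pd.DataFrame:
    """Apply :func:`length_ratios` to a lengths table with columns
    bud_id, group, outer_length, inner_length, bud_length."""
    rows = []
    for _, r in lengths.iterrows():
        out = {"bud_id": r["bud_id"], "group": r.get("group", "")}
        out.update(length_ratios(r.get("outer_length"), r.get("inner_length"),
                                 r.get("bud_length")))
        rows.append(out)
    return pd.DataFrame(rows)


def absolute_growth(series: pd.DataFrame) -> pd.DataFrame:
    """Per-interval area increase for every sepal of an area time series.

    Input columns: bud_id, sepal_id, position, time_h, area_um2 (plus any
    grouping columns, carried through). Growth over a consecutive interval
    is A(t1) - A(t0); negative deltas are clamped to 0 and flagged, since
    sepals at these stages grow monotonically and shrinkage indicates a
    segmentation error.
    """
    required = {"bud_id", "sepal_id", "position", "time_h", "area_um2"}
    missing = required - set(series.columns)
    if missing:
        raise ValueError(f"area series missing columns: {sorted(missing)}")
    if (series["area_um2"] <= 0).any():
        raise ValueError("areas must be positive")
    rows = []
    carry = [c for c in series.columns if c not in required]
    for (bud, sepal), grp in series.groupby(["bud_id", "sepal_id"], sort=True):
        grp = grp.sort_values("time_h")
        t = grp["time_h"].to_numpy(dtype=float)
        if np.any(np.diff(t) <= 0):
            raise ValueError(f"times must be strictly increasing for sepal {sepal}")
        a = grp["area_um2"].to_numpy(dtype=float)
        for i in range(len(t) - 1):
            delta = a[i + 1] - a[i]
            clamped = delta < 0
            row = {
                "bud_id": bud,
                "sepal_id": sepal,
                "position": grp["position"].iloc[0],
                "t0": t[i],
                "t1": t[i + 1],
                "area_t0": a[i],
                "area_t1": a[i + 1],
                "delta_area": max(delta, 0.0),
                "clamped": clamped,
            }
            for c in carry:
                row[c] = grp[c].iloc[0]
            rows.append(row)
    out = pd.DataFrame(rows)
    if not out.empty and out["clamped"].any():
        logger.warning("%d negative growth intervals clamped to 0",
                       int(out["clamped"].sum()))
    return out


def growth_contributions(deltas: pd.DataFrame) -> pd.DataFrame:
    """Fractional contribution of each sepal to a bud's total growth per interval.

    ``deltas`` is the output of :func:`absolute_growth` (or any frame with
    bud_id, sepal_id, t0, t1, delta_area). Contributions are each sepal's
    delta divided by the bud-interval total; an interval with zero total
    growth yields missing fractions and a warning.
    """
    out = deltas.copy()
    out["contribution"] = np.nan
    for (bud, t0, t1), grp in out.groupby(["bud_id", "t0", "t1"], sort=True):
        if len(grp) < 2:
            logger.warning("bud %s interval (%g, %g) has <2 sepals; skipped", bud, t0, t1)
            continue
        total = grp["delta_area"].sum()
        if total <= 0:
            logger.warning("bud %s interval (%g, %g) has zero total growth", bud, t0, t1)
            continue
        out.loc[grp.index, "contribution"] = grp["delta_area"] / total
    return out


def area_ratios(areas: Mapping[str, float] | pd.DataFrame,
                positions: Mapping[str, str] | None = None) -> dict[str, float]:
    """Outer/inner and outer/lateral area ratios at one timepoint.

    Accepts either ``{sepal_id: area}`` plus ``{sepal_id: position}``, or a
    frame with sepal_id, position, area_um2 columns. Exactly one outer
    sepal must be present. When a bud has two inner sepals their areas are
    summed into one before the outer/inner ratio (the merge rule). Lateral
    ratios are reported per lateral sepal.
    """
    if isinstance(areas, pd.DataFrame):
        positions = dict(zip(areas["sepal_id"], areas["position"]))
        areas = dict(zip(areas["sepal_id"], areas["area_um2"]))
    if positions is None:
        raise ValueError("positions are required")
    by_pos: dict[str, list[tuple[str, float]]] = {p: [] for p in POSITIONS}
    for sid, area in areas.items():
        pos = positions[sid]
        if pos not in by_pos:
            raise ValueError(f"unknown position {pos!r} for sepal {sid}")
        by_pos[pos].append((sid, float(area)))
    if len(by_pos["outer"]) != 1:
        raise ValueError("exactly one outer sepal required")
    outer = by_pos["outer"][0][1]
    ratios: dict[str, float] = {}
    inner_total = sum(a for _, a in by_pos["inner"])
    ratios["outer_over_inner"] = outer / inner_total if inner_total > 0 else math.nan
    for sid, a in sorted(by_pos["lateral"]):
        ratios[f"outer_over_lateral_{sid}"] = outer / a
    return ratios


def area_ratio_table(series: pd.DataFrame) -> pd.DataFrame:
    """Outer/inner and outer/lateral ratios for every (bud, timepoint)."""
    rows = []
    for (bud, t), grp in series.groupby(["bud_id", "time_h"], sort=True):
        r = area_ratios(grp)
        laterals = {k: v for k, v in r.items() if k.startswith("outer_over_lateral")}
        row = {"bud_id": bud, "time_h": t,
               "outer_over_inner": r["outer_over_inner"]}
        for i, (_, v) in enumerate(sorted(laterals.items()), start=1):
            row[f"outer_over_lateral_{i}"] = v
        rows.append(row)
    return pd.DataFrame(rows)


def exclude_uninitiated_buds(series: pd.DataFrame, check_time: float | None = None
                             ) -> pd.DataFrame:
    """Drop buds with no inner sepal observed by the second timepoint.

    Buds whose inner sepal has not initiated early on cannot contribute to
    growth-coordination metrics and reflect initiation, not elongation,
    variability.
    """
    keep = []
    for bud, grp in series.groupby("bud_id", sort=True):
        times = sorted(grp["time_h"].unique())
        cutoff = check_time if check_time is not None else (
            times[1] if len(times) > 1 else times[0])
        has_inner = not grp[(grp["position"] == "inner")
                            & (grp["time_h"] <= cutoff)].empty
        if has_inner:
            keep.append(bud)
        else:
            logger.warning("bud %s excluded: no inner sepal by t=%g h", bud, cutoff)
    return series[series["bud_id"].isin(keep)].copy()


def cell_growth_ratios(
    areas_t0: Mapping[str, float],
    areas_t1: Mapping[str, float],
    lineage: Mapping[str, str],
    display_range: tuple[float, float] = CELL_RATIO_DISPLAY_RANGE,
) -> pd.DataFrame:
    """Per-cell area growth ratios A(t1)/A(t0) over a lineage map.

    ``lineage`` maps each t1 cell label to its t0 parent label and must be
    one-to-one on tracked cells. Raw ratios are preserved; the ``display``
    column clamps to ``display_range`` for heat-map rendering only.
    Untracked cells are excluded with a warning.
    """
    parents = list(lineage.values())
    if len(set(parents)) != len(parents):
        raise ValueError("lineage map must be a bijection on tracked cells")
    lo, hi = display_range
    rows = []
    skipped = 0
    for child, parent in sorted(lineage.items()):
        if child not in areas_t1 or parent not in areas_t0:
            skipped += 1
            continue
        a0, a1 = float(areas_t0[parent]), float(areas_t1[child])
        if a0 <= 0:
            raise ValueError(f"cell {parent} has non-positive area at t0")
        ratio = a1 / a0
        rows.append({"cell_id": child, "parent_id": parent, "area_t0": a0,
                     "area_t1": a1, "ratio": ratio,
                     "display": min(max(ratio, lo), hi)})
    if skipped:
        logger.warning("%d lineage entries referenced untracked cells; excluded", skipped)
    untracked = set(areas_t1) - set(lineage)
    if untracked:
        logger.warning("%d t1 cells have no lineage entry; excluded", len(untracked))
    return pd.DataFrame(rows)
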