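"""Synthetic data generator for every input the pipeline consumes.

All generators emulate the statistical structure the analysis assumes, with
recorded ground truth, so each downstream stage can be tested end-to-end
without real data:

* ``simulate_sc`` — cluster-structured single-cell counts. Each cell draws
  a multinomial over genes whose expected proportions combine a baseline
  cluster profile, a multiplicative cell-cycle phase effect on phase genes,
  and hormone-responsive modules scaled by ``1 + beta*h`` (up sets) or
  ``max(floor, 1 - beta*h)`` (down sets), where ``h`` is a latent per-cell
  hormone-signaling level whose mean differs by genotype and cluster.
  Library sizes are log-normal; organelle genes carry configured expected
  fractions.
* ``simulate_spots`` — mixture spots: Dirichlet mixture weights over the
  cluster profiles, Poisson counts, and prediction scores equal to the true
  weights perturbed by Dirichlet noise of configurable concentration.
* ``simulate_nuclei`` — per-nucleus reporter tables with group-level target
  ratio mean and CV (gamma-distributed ratios; log-normal H2B totals).
* ``simulate_growth`` — exponential per-sepal area growth with position-
  and group-dependent rates and multiplicative measurement noise.

A single seed is threaded through all generators; sub-streams are derived
deterministically per component so identical seeds give byte-identical
outputs.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .io import (CountMatrix, GeneSet, GeneSetCollection, write_csv,
                 write_gene_sets, write_triplet)

PHASE_NAMES = ("G1", "S", "G2M")


def _rng(seed: int, stream: int) -> np.random.Generator:
    """Deterministic per-component substream of the global seed."""
    return np.random.default_rng([int(seed), int(stream)])


# ---------------------------------------------------------------------------
# Single-cell simulation
# ---------------------------------------------------------------------------

@dataclass
class HormoneSetSpec:
    """Sizes and latent coupling of one hormone's up/down gene sets.

    ``beta`` is the dimensionless slope linking the latent signaling level
    ``h`` to the expression fold of the sets: up genes scale by
    ``1 + beta*h`` and down genes by ``1 - beta*h`` (floored).
    """

    n_up: int = 25
    n_down: int = 25
    beta: float = 0.0

    def __post_init__(self) -> None:
        if self.n_up < 1 or self.n_down < 1:
            raise ValueError("hormone set sizes must be >= 1")


def _default_hormone_sets() -> dict[str, HormoneSetSpec]:
    # brassinosteroid carries the planted genotype-dependent signal by
    # default; auxin is an in-simulation null hormone.
    return {
        "brassinosteroid": HormoneSetSpec(25, 25, beta=0.25),
        "auxin": HormoneSetSpec(25, 25, beta=0.0),
    }


def _default_latent_mean(genotypes: Sequence[str], n_clusters: int
                         ) -> dict[str, np.ndarray]:
    """Reference genotype flat at 0; mutant shifted by +1 in cluster 1."""
    mu = {g: np.zeros(n_clusters) for g in genotypes}
    if len(genotypes) > 1 and n_clusters > 1:
        mu[genotypes[1]][1] = 1.0
    return mu


@dataclass
class ScSimConfig:
    """Configuration of the single-cell count simulator.

    ``n_cells_per_cluster`` is per cluster *and per genotype*. The gene
    universe is laid out as [mito | chloro | S | G2M | hormone sets |
    background] inside ``n_genes`` total genes.
    """

    n_genes: int = 1200
    n_cells_per_cluster: int = 150
    n_clusters: int = 5
    genotypes: tuple[str, ...] = ("WT", "drmy1")
    phase_gene_counts: Mapping[str, int] = field(
        default_factory=lambda: {"S": 25, "G2M": 25})
    phase_effect: float = 3.0
    hormone_sets: Mapping[str, HormoneSetSpec] = field(
        default_factory=_default_hormone_sets)
    latent_mean: Mapping[str, Sequence[float]] | None = None
    latent_sd: float = 0.5
    library_size_log_mean: float = math.log(6000.0)
    library_size_log_sd: float = 0.25
    mito_fraction: float = 0.03
    chloro_fraction: float = 0.05
    n_mito_genes: int = 10
    n_chloro_genes: int = 10
    down_floor: float = 0.05
    cluster_profile_sd: float = 0.4
    phase_probs: tuple[float, float, float] = (1 / 3, 1 / 3, 1 / 3)
    n_replicates: int = 2
    seed: int = 0

    def __post_init__(self) -> None:
        for name, val in (("n_genes", self.n_genes),
                          ("n_cells_per_cluster", self.n_cells_per_cluster),
                          ("n_clusters", self.n_clusters)):
            if val < 1:
                raise ValueError(f"{name} must be >= 1, got {val}")
        if len(self.genotypes) != 2:
            raise ValueError("exactly two genotypes are required")
        if self.phase_effect <= 0:
            raise ValueError("phase_effect must be > 0")
        if not 0 < self.down_floor < 1:
            raise ValueError("down_floor must lie in (0, 1)")
        for ph, n in self.phase_gene_counts.items():
            if ph not in ("S", "G2M"):
                raise ValueError(f"unknown phase {ph!r}")
            if n < 1:
                raise ValueError("phase gene counts must be >= 1")
        special = (self.n_mito_genes + self.n_chloro_genes
                   + sum(self.phase_gene_counts.values())
                   + sum(s.n_up + s.n_down for s in self.hormone_sets.values()))
        if special >= self.n_genes:
            raise ValueError(
                f"special genes ({special}) must leave room for background "
                f"genes within n_genes={self.n_genes}")
        if self.latent_mean is None:
            self.latent_mean = _default_latent_mean(self.genotypes, self.n_clusters)
        for g in self.genotypes:
            if len(np.asarray(self.latent_mean[g])) != self.n_clusters:
                raise ValueError("latent_mean must give one value per cluster")
        if not math.isclose(sum(self.phase_probs), 1.0, abs_tol=1e-9):
            raise ValueError("phase_probs must sum to 1")
        if self.mito_fraction + self.chloro_fraction >= 1:
            raise ValueError("organelle fractions must sum to < 1")


@dataclass
class GeneUniverse:
    """Index layout of the simulated gene universe."""

    gene_ids: np.ndarray
    mito_idx: np.ndarray
    chloro_idx: np.ndarray
    phase_idx: dict[str, np.ndarray]      # "S", "G2M"
    hormone_idx: dict[str, dict[str, np.ndarray]]  # hormone -> {"up","down"}

    def gene_sets(self) -> GeneSetCollection:
        sets = []
        for hormone in sorted(self.hormone_idx):
            for direction in ("up", "down"):
                idx = self.hormone_idx[hormone][direction]
                sets.append(GeneSet(hormone, direction,
                                    tuple(self.gene_ids[idx])))
        return GeneSetCollection(sets)

    def cc_gene_lists(self) -> tuple[list[str], list[str]]:
        return (list(self.gene_ids[self.phase_idx["S"]]),
                list(self.gene_ids[self.phase_idx["G2M"]]))


@dataclass
class SimTruth:
    """Ground truth recorded by :func:`simulate_sc`."""

    cells: pd.DataFrame                 # genotype, replicate, cluster, phase, latent_h
    universe: GeneUniverse
    cluster_profiles: np.ndarray        # clusters x genes baseline weights


def _build_universe(cfg: ScSimConfig) -> GeneUniverse:
    ids = []
    cursor = 0
    mito_idx = np.arange(cursor, cursor + cfg.n_mito_genes)
    ids += [f"ATMG{10 * (i + 1):05d}" for i in range(cfg.n_mito_genes)]
    cursor += cfg.n_mito_genes
    chloro_idx = np.arange(cursor, cursor + cfg.n_chloro_genes)
    ids += [f"ATCG{10 * (i + 1):05d}" for i in range(cfg.n_chloro_genes)]
    cursor += cfg.n_chloro_genes
    phase_idx = {}
    for ph in ("S", "G2M"):
        n = cfg.phase_gene_counts.get(ph, 0)
        phase_idx[ph] = np.arange(cursor, cursor + n)
        cursor += n
    hormone_idx: dict[str, dict[str, np.ndarray]] = {}
    for hormone in sorted(cfg.hormone_sets):
        spec = cfg.hormone_sets[hormone]
        up = np.arange(cursor, cursor + spec.n_up)
        cursor += spec.n_up
        down = np.arange(cursor, cursor + spec.n_down)
        cursor += spec.n_down
        hormone_idx[hormone] = {"up": up, "down": down}
    n_nuclear = cfg.n_genes - cfg.n_mito_genes - cfg.n_chloro_genes
    ids += [f"AT1G{10 * (i + 1):05d}" for i in range(n_nuclear)]
    return GeneUniverse(np.asarray(ids, dtype=object), mito_idx, chloro_idx,
                        phase_idx, hormone_idx)


def _baseline_profiles(cfg: ScSimConfig, uni: GeneUniverse,
                       rng: np.random.Generator) -> np.ndarray:
    """Per-cluster expected gene proportions (rows sum to 1).

    Nuclear genes draw gamma(2, 1) base weights with per-cluster log-normal
    jitter (the cluster structure); organelle genes are pinned so their
    expected fractions match the configured values in every cluster.
    """
    n_genes = cfg.n_genes
    organelle = np.zeros(n_genes, dtype=bool)
    organelle[uni.mito_idx] = True
    organelle[uni.chloro_idx] = True
    base = rng.gamma(2.0, 1.0, size=n_genes)
    mito_w = rng.gamma(2.0, 1.0, size=len(uni.mito_idx))
    chloro_w = rng.gamma(2.0, 1.0, size=len(uni.chloro_idx))
    profiles = np.empty((cfg.n_clusters, n_genes))
    for k in range(cfg.n_clusters):
        jitter = rng.lognormal(0.0, cfg.cluster_profile_sd, size=n_genes)
        w = base * jitter
        w[organelle] = 0.0
        nuclear_mass = 1.0 - cfg.mito_fraction - cfg.chloro_fraction
        w *= nuclear_mass / w.sum()
        if len(uni.mito_idx):
            w[uni.mito_idx] = cfg.mito_fraction * mito_w / mito_w.sum()
        if len(uni.chloro_idx):
            w[uni.chloro_idx] = cfg.chloro_fraction * chloro_w / chloro_w.sum()
        profiles[k] = w
    return profiles


def hormone_fold(weights: np.ndarray, uni: GeneUniverse,
                 cfg: ScSimConfig, h: float) -> np.ndarray:
    """Apply the latent-level hormone folds to one weight vector (copy)."""
    w = weights.copy()
    for hormone, spec in cfg.hormone_sets.items():
        idx = uni.hormone_idx[hormone]
        w[idx["up"]] *= max(cfg.down_floor, 1.0 + spec.beta * h)
        w[idx["down"]] *= max(cfg.down_floor, 1.0 - spec.beta * h)
    return w


def simulate_sc(cfg: ScSimConfig) -> tuple[CountMatrix, SimTruth]:
    """Simulate a genes x cells count matrix with recorded ground truth."""
    uni = _build_universe(cfg)
    rng_prof = _rng(cfg.seed, 1)
    rng_cell = _rng(cfg.seed, 2)
    profiles = _baseline_profiles(cfg, uni, rng_prof)

    n_cells = cfg.n_clusters * cfg.n_cells_per_cluster * len(cfg.genotypes)
    genotype = np.repeat(list(cfg.genotypes),
                         cfg.n_clusters * cfg.n_cells_per_cluster)
    cluster = np.tile(np.repeat(np.arange(cfg.n_clusters), cfg.n_cells_per_cluster),
                      len(cfg.genotypes))
    replicate = np.array([f"rep{1 + i % cfg.n_replicates}" for i in range(n_cells)],
                         dtype=object)
    phase = rng_cell.choice(PHASE_NAMES, size=n_cells, p=cfg.phase_probs)
    mu = np.array([np.asarray(cfg.latent_mean[g])[k]
                   for g, k in zip(genotype, cluster)])
    h = mu + cfg.latent_sd * rng_cell.standard_normal(n_cells)
    lib = np.maximum(
        1, np.round(rng_cell.lognormal(cfg.library_size_log_mean,
                                       cfg.library_size_log_sd,
                                       size=n_cells)).astype(np.int64))

    # per-cell expected proportions
    weights = profiles[cluster].copy()          # cells x genes
    for ph in ("S", "G2M"):
        idx = uni.phase_idx[ph]
        if len(idx):
            mask = phase == ph
            weights[np.ix_(mask, idx)] *= cfg.phase_effect
    for hormone, spec in cfg.hormone_sets.items():
        if spec.beta == 0.0:
            continue
        idx = uni.hormone_idx[hormone]
        up_fold = np.maximum(cfg.down_floor, 1.0 + spec.beta * h)
        down_fold = np.maximum(cfg.down_floor, 1.0 - spec.beta * h)
        weights[:, idx["up"]] *= up_fold[:, None]
        weights[:, idx["down"]] *= down_fold[:, None]
    weights /= weights.sum(axis=1, keepdims=True)

    counts = rng_cell.multinomial(lib, weights)  # cells x genes
    barcodes = np.asarray([f"BC{i:06d}" for i in range(n_cells)], dtype=object)
    cells = pd.DataFrame(
        {"genotype": genotype, "replicate": replicate, "cluster": cluster,
         "phase_truth": phase, "latent_h": h, "library_size": lib},
        index=barcodes)
    mito = np.zeros(cfg.n_genes, dtype=bool)
    mito[uni.mito_idx] = True
    chloro = np.zeros(cfg.n_genes, dtype=bool)
    chloro[uni.chloro_idx] = True
    flags = pd.DataFrame({"mito": mito, "chloro": chloro}, index=uni.gene_ids)
    matrix = CountMatrix(counts.T, uni.gene_ids, barcodes, flags,
                         cells[["genotype", "replicate", "cluster", "phase_truth"]])
    return matrix, SimTruth(cells, uni, profiles)


# ---------------------------------------------------------------------------
# Spatial spot simulation
# ---------------------------------------------------------------------------

@dataclass
class SpotSimConfig:
    """Configuration of the mixture-spot simulator.

    Spot expected profiles mix the single-cell cluster profiles (drawn from
    the embedded ``sc`` config) with Dirichlet weights; counts are Poisson.
    Genotype effects enter through the cluster profiles evaluated at the
    genotype's latent means, so a planted latent shift in ``sc`` surfaces
    as a genotype difference in the corresponding spot mixtures.
    ``score_concentration`` controls prediction-score noise (``None`` means
    noiseless scores equal to the true weights).
    """

    sc: ScSimConfig = field(default_factory=ScSimConfig)
    n_spots_per_area: int = 200
    n_capture_areas: int = 2
    dirichlet_alpha: float = 0.5
    library_size_log_mean: float = math.log(5000.0)
    library_size_log_sd: float = 0.3
    score_concentration: float | None = 50.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_spots_per_area < 1 or self.n_capture_areas < 1:
            raise ValueError("spot and area counts must be >= 1")
        if self.dirichlet_alpha <= 0:
            raise ValueError("dirichlet_alpha must be > 0")
        if self.score_concentration is not None and self.score_concentration <= 0:
            raise ValueError("score_concentration must be > 0 or None")


@dataclass
class SpotTruth:
    spots: pd.DataFrame          # spot_id, array_col, array_row, capture_area, genotype
    weights: pd.DataFrame        # spots x clusters true mixture weights
    universe: GeneUniverse


def simulate_spots(cfg: SpotSimConfig
                   ) -> tuple[CountMatrix, pd.DataFrame, SpotTruth]:
    """Simulate spot counts, prediction scores, and the mixture truth."""
    sc = cfg.sc
    uni = _build_universe(sc)
    rng_prof = _rng(cfg.seed, 11)
    rng_spot = _rng(cfg.seed, 12)
    base_profiles = _baseline_profiles(sc, uni, rng_prof)

    cluster_labels = [f"cluster_{k}" for k in range(sc.n_clusters)]
    n_spots = cfg.n_spots_per_area * cfg.n_capture_areas
    area = np.repeat([f"area{i + 1}" for i in range(cfg.n_capture_areas)],
                     cfg.n_spots_per_area)
    genotype = np.array([sc.genotypes[i % len(sc.genotypes)]
                         for i in range(cfg.n_capture_areas)], dtype=object)
    spot_genotype = np.repeat(genotype, cfg.n_spots_per_area)

    # genotype-specific cluster profiles at the deterministic latent means
    profiles = {}
    for g in sc.genotypes:
        mat = np.empty_like(base_profiles)
        for k in range(sc.n_clusters):
            w = hormone_fold(base_profiles[k], uni, sc,
                             float(np.asarray(sc.latent_mean[g])[k]))
            mat[k] = w / w.sum()
        profiles[g] = mat

    weights = rng_spot.dirichlet(np.full(sc.n_clusters, cfg.dirichlet_alpha),
                                 size=n_spots)
    lib = np.maximum(
        1, np.round(rng_spot.lognormal(cfg.library_size_log_mean,
                                       cfg.library_size_log_sd,
                                       size=n_spots)).astype(np.int64))
    expected = np.empty((n_spots, sc.n_genes))
    for g in sc.genotypes:
        mask = spot_genotype == g
        expected[mask] = weights[mask] @ profiles[g]
    counts = rng_spot.poisson(lib[:, None] * expected)

    if cfg.score_concentration is None or math.isinf(cfg.score_concentration):
        scores = weights.copy()
    else:
        scores = np.vstack([
            rng_spot.dirichlet(cfg.score_concentration * w + 1e-9)
            for w in weights])

    spot_ids = np.asarray([f"SPOT{i:05d}" for i in range(n_spots)], dtype=object)
    side = int(math.ceil(math.sqrt(cfg.n_spots_per_area)))
    within = np.tile(np.arange(cfg.n_spots_per_area), cfg.n_capture_areas)
    spots = pd.DataFrame(
        {"spot_id": spot_ids, "array_col": within % side,
         "array_row": within // side, "capture_area": area,
         "genotype": spot_genotype}).set_index("spot_id")
    mito = np.zeros(sc.n_genes, dtype=bool)
    mito[uni.mito_idx] = True
    chloro = np.zeros(sc.n_genes, dtype=bool)
    chloro[uni.chloro_idx] = True
    flags = pd.DataFrame({"mito": mito, "chloro": chloro}, index=uni.gene_ids)
    matrix = CountMatrix(counts.T, uni.gene_ids, spot_ids, flags, spots)
    scores_df = pd.DataFrame(scores, index=spot_ids, columns=cluster_labels)
    weights_df = pd.DataFrame(weights, index=spot_ids, columns=cluster_labels)
    return matrix, scores_df, SpotTruth(spots, weights_df, uni)


# ---------------------------------------------------------------------------
# Nucleus reporter simulation
# ---------------------------------------------------------------------------

@dataclass
class NucleiSimConfig:
    """Group-level target ratio mean and CV for the reporter simulator.

    Ratios are gamma-distributed with the exact target mean and CV (a CV of
    0 gives a constant ratio); H2B totals are log-normal and BES1 is the
    ratio times the H2B total.
    """

    groups: Mapping[str, tuple[float, float]] = field(
        default_factory=lambda: {"WT": (1.0, 0.2), "drmy1": (1.3, 0.35)})
    n_sepals_per_group: int = 20
    nuclei_per_sepal: int = 50
    h2b_log_mean: float = math.log(5000.0)
    h2b_log_sd: float = 0.3
    positions: tuple[str, ...] = ("outer", "inner", "lateral", "lateral")
    seed: int = 0

    def __post_init__(self) -> None:
        for g, (mean, cv) in self.groups.items():
            if mean <= 0:
                raise ValueError(f"group {g}: target mean must be > 0")
            if cv < 0:
                raise ValueError(f"group {g}: target CV must be >= 0")
        if self.n_sepals_per_group < 1 or self.nuclei_per_sepal < 1:
            raise ValueError("sepal and nucleus counts must be >= 1")


def simulate_nuclei(cfg: NucleiSimConfig) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Simulate a nucleus table; returns (records, per-sepal truth)."""
    rng = _rng(cfg.seed, 21)
    records = []
    truth = []
    for group in sorted(cfg.groups):
        mean, cv = cfg.groups[group]
        for s in range(cfg.n_sepals_per_group):
            sepal_id = f"{group}_sepal{s:03d}"
            bud_id = f"{group}_bud{s // len(cfg.positions):03d}"
            position = cfg.positions[s % len(cfg.positions)]
            if cv == 0:
                ratios = np.full(cfg.nuclei_per_sepal, mean)
            else:
                shape = 1.0 / cv ** 2
                ratios = rng.gamma(shape, mean * cv ** 2,
                                   size=cfg.nuclei_per_sepal)
            h2b = rng.lognormal(cfg.h2b_log_mean, cfg.h2b_log_sd,
                                size=cfg.nuclei_per_sepal)
            for i in range(cfg.nuclei_per_sepal):
                records.append({
                    "nucleus_id": f"{sepal_id}_n{i:03d}",
                    "bud_id": bud_id, "sepal_id": sepal_id,
                    "position": position, "group": group,
                    "bes1_signal": ratios[i] * h2b[i],
                    "h2b_signal": h2b[i]})
            truth.append({"sepal_id": sepal_id, "group": group,
                          "position": position, "target_mean": mean,
                          "target_cv": cv})
    return pd.DataFrame(records), pd.DataFrame(truth)


# ---------------------------------------------------------------------------
# Growth simulation
# ---------------------------------------------------------------------------

def _default_growth_rates() -> dict[str, dict[str, float]]:
    # per-hour exponential area growth rates by sepal position
    return {
        "mock": {"outer": 0.06, "inner": 0.02, "lateral": 0.03},
    }


@dataclass
class GrowthSimConfig:
    """Exponential sepal-area growth: A(t) = A(0) * exp(g*t) * noise.

    ``rates`` maps group -> position -> per-hour rate; each bud carries an
    outer, an inner (or two when ``two_inner_prob`` fires) and two lateral
    sepals. Noise is multiplicative log-normal with sd ``noise_sd``.
    """

    rates: Mapping[str, Mapping[str, float]] = field(
        default_factory=_default_growth_rates)
    initial_area: float = 100.0
    timepoints: tuple[float, ...] = (0.0, 12.0, 24.0, 36.0)
    noise_sd: float = 0.02
    n_buds_per_group: int = 20
    two_inner_prob: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.initial_area <= 0:
            raise ValueError("initial_area must be > 0")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if sorted(self.timepoints) != list(self.timepoints) or len(self.timepoints) < 2:
            raise ValueError("timepoints must be increasing with >= 2 entries")


def simulate_growth(cfg: GrowthSimConfig) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Simulate per-sepal area time series; returns (series, per-sepal truth)."""
    rng = _rng(cfg.seed, 31)
    rows = []
    truth = []
    for group in sorted(cfg.rates):
        rates = cfg.rates[group]
        for b in range(cfg.n_buds_per_group):
            bud_id = f"{group}_bud{b:03d}"
            two_inner = rng.random() < cfg.two_inner_prob
            sepals = [("outer", "outer")]
            if two_inner:
                sepals += [("inner_a", "inner"), ("inner_b", "inner")]
            else:
                sepals += [("inner", "inner")]
            sepals += [("lateral1", "lateral"), ("lateral2", "lateral")]
            for name, pos in sepals:
                g = rates[pos]
                a0 = cfg.initial_area * (0.5 if two_inner and pos == "inner" else 1.0)
                sepal_id = f"{bud_id}_{name}"
                truth.append({"sepal_id": sepal_id, "bud_id": bud_id,
                              "group": group, "position": pos, "rate": g,
                              "initial_area": a0})
                for t in cfg.timepoints:
                    noise = (math.exp(cfg.noise_sd * rng.standard_normal())
                             if cfg.noise_sd > 0 else 1.0)
                    rows.append({"bud_id": bud_id, "group": group,
                                 "sepal_id": sepal_id, "position": pos,
                                 "time_h": t,
                                 "area_um2": a0 * math.exp(g * t) * noise})
    return pd.DataFrame(rows), pd.DataFrame(truth)


# ---------------------------------------------------------------------------
# Writers
# ---------------------------------------------------------------------------

def write_sc(matrix: CountMatrix, truth: SimTruth, outdir: str | Path,
             header_lines: Sequence[str] = ()) -> Path:
    """Write the triplet, metadata, gene-set and cc-gene files plus truth."""
    outdir = Path(outdir)
    write_triplet(matrix, outdir)
    meta = matrix.cell_meta.copy()
    meta.insert(0, "barcode", matrix.cell_ids)
    write_csv(meta, outdir / "metadata.csv", header_lines)
    write_csv(truth.cells.reset_index(names="barcode"),
              outdir / "truth_cells.csv", header_lines)
    write_gene_sets(truth.universe.gene_sets(), outdir / "hormone_sets.tsv")
    s, g2m = truth.universe.cc_gene_lists()
    cc = pd.DataFrame({"gene": s + g2m, "phase": ["S"] * len(s) + ["G2M"] * len(g2m)})
    cc.to_csv(outdir / "cc_genes.tsv", sep="\t", header=False, index=False)
    return outdir


def write_spots(matrix: CountMatrix, scores: pd.DataFrame, truth: SpotTruth,
                outdir: str | Path, header_lines: Sequence[str] = ()) -> Path:
    outdir = Path(outdir)
    write_triplet(matrix, outdir)
    write_csv(truth.spots.reset_index(), outdir / "spots.csv", header_lines)
    write_csv(scores.reset_index(names="spot_id"),
              outdir / "prediction_scores.csv", header_lines)
    write_csv(truth.weights.reset_index(names="spot_id"),
              outdir / "truth_weights.csv", header_lines)
    write_gene_sets(truth.universe.gene_sets(), outdir / "hormone_sets.tsv")
    return outdir


def write_nuclei(records: pd.DataFrame, truth: pd.DataFrame,
                 outdir: str | Path, header_lines: Sequence[str] = ()) -> Path:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    write_csv(records, outdir / "nuclei.csv", header_lines)
    write_csv(truth, outdir / "truth_nuclei.csv", header_lines)
    return outdir


def write_growth(series: pd.DataFrame, truth: pd.DataFrame,
                 outdir: str | Path, header_lines: Sequence[str] = ()) -> Path:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    write_csv(series, outdir / "areas.csv", header_lines)
    write_csv(truth, outdir / "truth_growth.csv", header_lines)
    return outdir
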