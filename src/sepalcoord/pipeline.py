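"""End-to-end orchestration of the analysis stages with one config.

``run_all`` executes simulate (optional) -> qc -> cellcycle -> score ->
spatial -> reporter -> growth in order, skipping disabled stages, and
writes a machine-readable JSON run report (input checksums, parameters,
row counts, warnings). Every CSV output carries a header comment with the
package version, seed, and a parameter digest; re-running with the same
config and seed reproduces byte-identical outputs.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import sys
import tomllib
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from . import __version__
from .io import read_csv, read_gene_sets, read_triplet, write_csv
from . import cell_cycle, growth, hormone, qc, reporter, spatial, synthetic

logger = logging.getLogger("sepalcoord")

ALL_STAGES = ("simulate", "qc", "cellcycle", "score", "spatial", "reporter", "growth")


def setup_logging(outdir: Path | None = None, level: int = logging.INFO) -> None:
    """Structured logging to console and, when given, a run log file."""
    root = logging.getLogger("sepalcoord")
    root.setLevel(level)
    root.handlers.clear()
    fmt = logging.Formatter("%(asctime)s %(levelname)s %(name)s: %(message)s")
    console = logging.StreamHandler(sys.stderr)
    console.setFormatter(fmt)
    root.addHandler(console)
    if outdir is not None:
        outdir.mkdir(parents=True, exist_ok=True)
        fh = logging.FileHandler(outdir / "run.log", mode="w")
        fh.setFormatter(fmt)
        root.addHandler(fh)


@dataclass
class RunConfig:
    """All knobs of one pipeline run."""

    outdir: str = "sepalcoord_run"
    seed: int = 0
    stages: dict[str, bool] = field(
        default_factory=lambda: {s: True for s in ALL_STAGES})
    # QC thresholds
    min_genes: int = 600
    max_genes: int = 6000
    max_mito_pct: float = 10.0
    max_chloro_pct: float = 20.0
    # cell cycle
    cc_threshold: float = 0.03
    # contrasts
    alpha: float = 0.05
    # spatial
    min_spots: int = 10
    area_flag_factor: float = 2.0
    # reporter
    min_nuclei: int = 5
    # external inputs (used when simulate is disabled)
    sc_dir: str | None = None
    spots_dir: str | None = None
    nuclei_csv: str | None = None
    areas_csv: str | None = None
    gene_sets_file: str | None = None
    cc_genes_file: str | None = None

    @classmethod
    def from_toml(cls, path: str | Path) -> "RunConfig":
        with open(path, "rb") as fh:
            raw = tomllib.load(fh)
        flat: dict = {}
        for key, value in raw.items():
            if isinstance(value, dict) and key != "stages":
                flat.update(value)
            else:
                flat[key] = value
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(flat) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**flat)

    def digest(self) -> str:
        # analysis parameters only: the output path must not change it
        params = {k: v for k, v in dataclasses.asdict(self).items()
                  if k != "outdir"}
        payload = json.dumps(params, sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:12]

    def header_lines(self) -> list[str]:
        return [f"sepalcoord v{__version__}",
                f"seed={self.seed} params_digest={self.digest()}"]


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()[:16]


class _WarningCounter(logging.Handler):
    def __init__(self) -> None:
        super().__init__(level=logging.WARNING)
        self.messages: list[str] = []

    def emit(self, record: logging.LogRecord) -> None:
        self.messages.append(record.getMessage())


def run_all(config: RunConfig) -> dict:
    """Run the enabled stages in order; return (and write) the run report."""
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    setup_logging(outdir)
    counter = _WarningCounter()
    logging.getLogger("sepalcoord").addHandler(counter)
    hdr = config.header_lines()
    report: dict = {
        "version": __version__,
        "seed": config.seed,
        "params_digest": config.digest(),
        "stages_completed": [],
        "row_counts": {},
        "output_checksums": {},
        "warnings": counter.messages,
    }
    enabled = {s: config.stages.get(s, True) for s in ALL_STAGES}
    state: dict = {}
    current = None
    try:
        for stage in ALL_STAGES:
            if not enabled[stage]:
                logger.info("stage %s disabled; skipping", stage)
                continue
            current = stage
            logger.info("stage %s starting", stage)
            _STAGE_FUNCS[stage](config, outdir, hdr, state, report)
            report["stages_completed"].append(stage)
    except Exception as exc:
        raise RuntimeError(f"pipeline halted in stage {current!r}: {exc}") from exc
    finally:
        logging.getLogger("sepalcoord").removeHandler(counter)
    for f in sorted(outdir.rglob("*.csv")):
        report["output_checksums"][str(f.relative_to(outdir))] = _sha256(f)
    with open(outdir / "run_report.json", "w") as fh:
        json.dump(report, fh, indent=2, sort_keys=True)
    return report


# -- individual stages -------------------------------------------------------

def _stage_simulate(cfg, outdir, hdr, state, report):
    sc_cfg = synthetic.ScSimConfig(seed=cfg.seed)
    matrix, truth = synthetic.simulate_sc(sc_cfg)
    synthetic.write_sc(matrix, truth, outdir / "sim" / "sc", hdr)
    spot_cfg = synthetic.SpotSimConfig(sc=sc_cfg, seed=cfg.seed)
    smatrix, scores, struth = synthetic.simulate_spots(spot_cfg)
    synthetic.write_spots(smatrix, scores, struth, outdir / "sim" / "spots", hdr)
    nuclei, ntruth = synthetic.simulate_nuclei(synthetic.NucleiSimConfig(seed=cfg.seed))
    synthetic.write_nuclei(nuclei, ntruth, outdir / "sim" / "nuclei", hdr)
    areas, gtruth = synthetic.simulate_growth(synthetic.GrowthSimConfig(seed=cfg.seed))
    synthetic.write_growth(areas, gtruth, outdir / "sim" / "growth", hdr)
    state.update(sc=(matrix, truth), spots=(smatrix, scores, struth),
                 nuclei=nuclei, areas=areas)
    report["row_counts"]["simulate_cells"] = matrix.n_cells
    report["row_counts"]["simulate_spots"] = smatrix.n_cells
    report["row_counts"]["simulate_nuclei"] = len(nuclei)
    report["row_counts"]["simulate_area_obs"] = len(areas)


def _load_sc(cfg, state):
    if "sc" in state:
        return state["sc"][0]
    if cfg.sc_dir is None:
        raise ValueError("no single-cell input: enable simulate or set sc_dir")
    meta = None
    meta_path = Path(cfg.sc_dir) / "metadata.csv"
    if meta_path.exists():
        meta = read_csv(meta_path).set_index("barcode")
    return read_triplet(cfg.sc_dir, cell_meta=meta)


def _stage_qc(cfg, outdir, hdr, state, report):
    matrix = _load_sc(cfg, state)
    thresholds = qc.QcThresholds(cfg.min_genes, cfg.max_genes,
                                 cfg.max_mito_pct, cfg.max_chloro_pct)
    retained, removals = qc.filter_cells(matrix, thresholds)
    mito, chloro = qc.organelle_fractions(matrix)
    summary = pd.DataFrame({
        "barcode": matrix.cell_ids,
        "detected_genes": matrix.detected_genes_per_cell(),
        "total_counts": matrix.total_counts(),
        "mito_pct": mito, "chloro_pct": chloro,
        "retained": [b in set(retained) for b in matrix.cell_ids]})
    write_csv(summary, outdir / "qc" / "qc_summary.csv", hdr)
    write_csv(pd.DataFrame({"barcode": retained}),
              outdir / "qc" / "retained_barcodes.csv", hdr)
    state["qc_matrix"] = matrix.select_cells(retained)
    report["row_counts"]["qc_retained_cells"] = len(retained)
    report["row_counts"]["qc_removals"] = removals


def _gene_sets(cfg, state):
    if cfg.gene_sets_file is not None:
        return read_gene_sets(cfg.gene_sets_file)
    if "sc" in state:
        return state["sc"][1].universe.gene_sets()
    raise ValueError("no gene sets: set gene_sets_file or enable simulate")


def _cc_lists(cfg, state):
    if cfg.cc_genes_file is not None:
        return cell_cycle.read_cc_gene_list(cfg.cc_genes_file)
    if "sc" in state:
        return state["sc"][1].universe.cc_gene_lists()
    raise ValueError("no cell-cycle gene list: set cc_genes_file or enable simulate")


def _stage_cellcycle(cfg, outdir, hdr, state, report):
    matrix = state.get("qc_matrix") or _load_sc(cfg, state)
    s_genes, g2m_genes = _cc_lists(cfg, state)
    phases = cell_cycle.score_phases(matrix, s_genes, g2m_genes, seed=cfg.seed)
    reduced, var_report = cell_cycle.remove_cc_genes(
        matrix, phases.phases.to_numpy(), threshold=cfg.cc_threshold)
    write_csv(phases.table.reset_index(names="barcode"),
              outdir / "cellcycle" / "phases.csv",
              hdr + [f"cc_threshold={cfg.cc_threshold} scale=log1p_cp10k"])
    write_csv(var_report, outdir / "cellcycle" / "variance_report.csv",
              hdr + [f"cc_threshold={cfg.cc_threshold} scale=log1p_cp10k"])
    state["cc_matrix"] = reduced
    report["row_counts"]["cellcycle_genes_removed"] = int(var_report["removed"].sum())
    report["row_counts"]["cellcycle_genes_kept"] = reduced.n_genes


def _stage_score(cfg, outdir, hdr, state, report):
    matrix = state.get("cc_matrix") or state.get("qc_matrix") or _load_sc(cfg, state)
    sets = _gene_sets(cfg, state)
    fractions = hormone.score_cells(matrix, sets)
    table = hormone.contrast_clusters(
        fractions, matrix.cell_meta["cluster"], matrix.cell_meta["genotype"],
        alpha=cfg.alpha)
    calls = hormone.direction_calls(table)
    fam = [f"alpha={table.attrs['alpha']} "
           f"bonferroni_family={table.attrs['n_tests']} "
           f"threshold={table.attrs['bonferroni_threshold']:.6g} "
           f"star_family={table.attrs['star_family']}"]
    write_csv(fractions.reset_index(names="barcode"),
              outdir / "score" / "cell_fractions.csv", hdr)
    write_csv(table, outdir / "score" / "contrasts.csv", hdr + fam)
    write_csv(calls, outdir / "score" / "direction_calls.csv", hdr)
    hormone.dot_plot(table, outdir / "score" / "dotplot.png")
    state["contrasts"] = table
    report["row_counts"]["score_contrast_rows"] = len(table)
    report["row_counts"]["score_significant_rows"] = int(table["significant"].sum())


def _stage_spatial(cfg, outdir, hdr, state, report):
    if "spots" in state:
        smatrix, scores, struth = state["spots"]
    else:
        if cfg.spots_dir is None:
            raise ValueError("no spatial input: enable simulate or set spots_dir")
        sdir = Path(cfg.spots_dir)
        meta = read_csv(sdir / "spots.csv").set_index("spot_id")
        smatrix = read_triplet(sdir, cell_meta=meta)
        scores = read_csv(sdir / "prediction_scores.csv").set_index("spot_id")
    sets = _gene_sets(cfg, state)
    area_summary, flagged = spatial.spot_qc(
        smatrix, smatrix.cell_meta["capture_area"], cfg.area_flag_factor)
    keep = ~smatrix.cell_meta["capture_area"].isin(flagged).to_numpy()
    smatrix = smatrix.subset_cells(keep)
    scores = scores.loc[smatrix.cell_ids]
    labels = spatial.best_cluster(scores)
    props = spatial.cluster_spot_proportions(
        labels, smatrix.cell_meta["genotype"], min_spots=cfg.min_spots)
    fractions, contrasts = spatial.score_spots(
        smatrix, sets, labels, smatrix.cell_meta["genotype"], alpha=cfg.alpha)
    write_csv(area_summary, outdir / "spatial" / "area_qc.csv", hdr)
    write_csv(labels.reset_index().rename(columns={"index": "spot_id"}),
              outdir / "spatial" / "best_cluster.csv", hdr)
    write_csv(props, outdir / "spatial" / "cluster_proportions.csv",
              hdr + [f"min_spots={cfg.min_spots}"])
    write_csv(contrasts, outdir / "spatial" / "contrasts.csv",
              hdr + [f"bonferroni_threshold={contrasts.attrs['bonferroni_threshold']:.6g}"])
    report["row_counts"]["spatial_spots_kept"] = smatrix.n_cells
    report["row_counts"]["spatial_flagged_areas"] = len(flagged)
    report["row_counts"]["spatial_proportion_rows"] = len(props)


def _stage_reporter(cfg, outdir, hdr, state, report):
    if "nuclei" in state:
        nuclei = state["nuclei"]
    else:
        if cfg.nuclei_csv is None:
            raise ValueError("no nuclei input: enable simulate or set nuclei_csv")
        nuclei = reporter.read_nuclei(cfg.nuclei_csv)
    summaries = reporter.sepal_summary(nuclei, min_nuclei=cfg.min_nuclei)
    comparisons = reporter.group_compare(summaries, by="position")
    write_csv(summaries, outdir / "reporter" / "sepal_summary.csv",
              hdr + ["cv=sample_sd/mean (ddof=1)"])
    write_csv(comparisons, outdir / "reporter" / "comparisons.csv", hdr)
    report["row_counts"]["reporter_sepals"] = len(summaries)
    report["row_counts"]["reporter_comparisons"] = len(comparisons)


def _stage_growth(cfg, outdir, hdr, state, report):
    if "areas" in state:
        areas = state["areas"]
    else:
        if cfg.areas_csv is None:
            raise ValueError("no areas input: enable simulate or set areas_csv")
        areas = read_csv(cfg.areas_csv)
    areas = growth.exclude_uninitiated_buds(areas)
    deltas = growth.absolute_growth(areas)
    contributions = growth.growth_contributions(deltas)
    ratios = growth.area_ratio_table(areas)
    write_csv(contributions, outdir / "growth" / "growth_records.csv", hdr)
    write_csv(ratios, outdir / "growth" / "area_ratios.csv", hdr)
    report["row_counts"]["growth_intervals"] = len(contributions)
    report["row_counts"]["growth_ratio_rows"] = len(ratios)


_STAGE_FUNCS = {
    "simulate": _stage_simulate,
    "qc": _stage_qc,
    "cellcycle": _stage_cellcycle,
    "score": _stage_score,
    "spatial": _stage_spatial,
    "reporter": _stage_reporter,
    "growth": _stage_growth,
}
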