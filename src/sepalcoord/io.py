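"""Shared containers and on-disk formats.

The package's count data travel as a :class:`CountMatrix`: a genes x cells
(or genes x spots) sparse integer matrix plus gene/cell annotations. On disk
this is the cellranger-style MatrixMarket triplet (``matrix.mtx``,
``features.tsv``, ``barcodes.tsv``) with cell metadata in a separate CSV.

Hormone-response gene sets are collections of (hormone, direction, genes)
records read from GMT or three-column TSV files.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse as sp

logger = logging.getLogger("sepalcoord")

#: Default id-prefix rules tagging organelle genes (TAIR chromosome tags).
MITO_PATTERN = r"^ATMG"
CHLORO_PATTERN = r"^ATCG"


@dataclass
class CountMatrix:
    """Genes x cells sparse non-negative integer count matrix with annotations.

    Parameters
    ----------
    counts
        ``(n_genes, n_cells)`` sparse matrix of raw transcript counts.
    gene_ids
        Unique gene identifiers, one per row.
    cell_ids
        Unique cell/spot barcodes, one per column.
    gene_flags
        Boolean frame indexed by gene id with at least ``mito`` and
        ``chloro`` columns.
    cell_meta
        Per-cell labels (genotype, replicate, cluster, ...) indexed by barcode.
    """

    counts: sp.csr_matrix
    gene_ids: np.ndarray
    cell_ids: np.ndarray
    gene_flags: pd.DataFrame
    cell_meta: pd.DataFrame = field(default_factory=pd.DataFrame)

    def __post_init__(self) -> None:
        self.counts = sp.csr_matrix(self.counts)
        self.gene_ids = np.asarray(self.gene_ids, dtype=object)
        self.cell_ids = np.asarray(self.cell_ids, dtype=object)
        if self.counts.shape != (len(self.gene_ids), len(self.cell_ids)):
            raise ValueError(
                f"counts shape {self.counts.shape} does not match "
                f"{len(self.gene_ids)} genes x {len(self.cell_ids)} cells"
            )
        if self.counts.nnz and self.counts.data.min() < 0:
            raise ValueError("negative counts are not allowed")
        if len(set(self.gene_ids)) != len(self.gene_ids):
            raise ValueError("gene_ids must be unique")
        if len(set(self.cell_ids)) != len(self.cell_ids):
            raise ValueError("cell_ids must be unique")
        if self.gene_flags is None or self.gene_flags.empty:
            self.gene_flags = pd.DataFrame(
                {"mito": False, "chloro": False}, index=self.gene_ids
            )
        for col in ("mito", "chloro"):
            if col not in self.gene_flags.columns:
                raise ValueError(f"gene_flags missing required column {col!r}")
        if len(self.gene_flags) != len(self.gene_ids):
            raise ValueError("gene_flags length does not match gene_ids")
        self.gene_flags = self.gene_flags.set_axis(self.gene_ids, axis=0)
        if self.cell_meta is None or len(self.cell_meta) == 0:
            self.cell_meta = pd.DataFrame(index=self.cell_ids)
        elif len(self.cell_meta) != len(self.cell_ids):
            raise ValueError("cell_meta length does not match cell_ids")
        else:
            self.cell_meta = self.cell_meta.set_axis(self.cell_ids, axis=0)

    # -- basic views -------------------------------------------------------

    @property
    def n_genes(self) -> int:
        return self.counts.shape[0]

    @property
    def n_cells(self) -> int:
        return self.counts.shape[1]

    def total_counts(self) -> np.ndarray:
        """Per-cell library sizes (column sums)."""
        return np.asarray(self.counts.sum(axis=0)).ravel()

    def detected_genes_per_cell(self) -> np.ndarray:
        """Number of genes with count > 0 in each cell."""
        return np.asarray((self.counts > 0).sum(axis=0)).ravel()

    def gene_indices(self, gene_set: Iterable[str], warn: bool = True) -> np.ndarray:
        """Resolve gene ids to row indices; unknown ids are ignored (warned)."""
        index = {g: i for i, g in enumerate(self.gene_ids)}
        wanted = list(gene_set)
        hits = [index[g] for g in wanted if g in index]
        missing = len(wanted) - len(hits)
        if missing and warn:
            logger.warning("%d of %d gene-set ids not present in matrix", missing, len(wanted))
        return np.asarray(sorted(set(hits)), dtype=int)

    def subset_genes(self, keep: np.ndarray) -> "CountMatrix":
        keep = np.asarray(keep)
        if keep.dtype == bool:
            keep = np.flatnonzero(keep)
        return CountMatrix(
            counts=self.counts[keep, :],
            gene_ids=self.gene_ids[keep],
            cell_ids=self.cell_ids,
            gene_flags=self.gene_flags.iloc[keep],
            cell_meta=self.cell_meta,
        )

    def subset_cells(self, keep: np.ndarray) -> "CountMatrix":
        keep = np.asarray(keep)
        if keep.dtype == bool:
            keep = np.flatnonzero(keep)
        return CountMatrix(
            counts=self.counts[:, keep],
            gene_ids=self.gene_ids,
            cell_ids=self.cell_ids[keep],
            gene_flags=self.gene_flags,
            cell_meta=self.cell_meta.iloc[keep],
        )

    def select_cells(self, barcodes: Sequence[str]) -> "CountMatrix":
        index = {b: i for i, b in enumerate(self.cell_ids)}
        return self.subset_cells(np.asarray([index[b] for b in barcodes], dtype=int))


# ---------------------------------------------------------------------------
# MatrixMarket triplet IO
# ---------------------------------------------------------------------------

def write_triplet(matrix: CountMatrix, outdir: str | Path) -> Path:
    """Write a cellranger-style triplet (matrix.mtx / features.tsv / barcodes.tsv)."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    coo = matrix.counts.tocoo()
    scipy.io.mmwrite(str(outdir / "matrix.mtx"), coo, field="integer")
    flags = np.where(
        matrix.gene_flags["mito"].to_numpy(),
        "mito",
        np.where(matrix.gene_flags["chloro"].to_numpy(), "chloro", "nuclear"),
    )
    feats = pd.DataFrame(
        {"gene_id": matrix.gene_ids, "gene_name": matrix.gene_ids, "flag": flags}
    )
    feats.to_csv(outdir / "features.tsv", sep="\t", header=False, index=False)
    pd.Series(matrix.cell_ids).to_csv(
        outdir / "barcodes.tsv", sep="\t", header=False, index=False
    )
    return outdir


def read_triplet(
    indir: str | Path,
    cell_meta: pd.DataFrame | None = None,
    mito_pattern: str = MITO_PATTERN,
    chloro_pattern: str = CHLORO_PATTERN,
) -> CountMatrix:
    """Read a cellranger-style triplet from ``indir``.

    Organelle flags come from the third features column when present
    (values ``mito``/``chloro``); otherwise from the id-prefix regexes.
    """
    indir = Path(indir)
    counts = sp.csr_matrix(scipy.io.mmread(indir / "matrix.mtx"))
    feats = pd.read_csv(indir / "features.tsv", sep="\t", header=None, dtype=str)
    gene_ids = feats.iloc[:, 0].to_numpy(dtype=object)
    if feats.shape[1] >= 3:
        flag_col = feats.iloc[:, 2].fillna("")
        mito = (flag_col == "mito").to_numpy()
        chloro = (flag_col == "chloro").to_numpy()
    else:
        mito = np.array([bool(re.match(mito_pattern, g)) for g in gene_ids])
        chloro = np.array([bool(re.match(chloro_pattern, g)) for g in gene_ids])
    barcodes = pd.read_csv(indir / "barcodes.tsv", sep="\t", header=None, dtype=str)
    cell_ids = barcodes.iloc[:, 0].to_numpy(dtype=object)
    flags = pd.DataFrame({"mito": mito, "chloro": chloro}, index=gene_ids)
    meta = pd.DataFrame(index=cell_ids)
    if cell_meta is not None:
        meta = cell_meta.reindex(cell_ids)
    return CountMatrix(counts, gene_ids, cell_ids, flags, meta)


# ---------------------------------------------------------------------------
# Hormone-response gene sets
# ---------------------------------------------------------------------------

VALID_DIRECTIONS = ("up", "down")


@dataclass(frozen=True)
class GeneSet:
    hormone: str
    direction: str
    genes: tuple[str, ...]

    def __post_init__(self) -> None:
        if self.direction not in VALID_DIRECTIONS:
            raise ValueError(f"direction must be one of {VALID_DIRECTIONS}")
        if not self.genes:
            raise ValueError(f"gene set {self.key} is empty")

    @property
    def key(self) -> str:
        return f"{self.hormone}_{self.direction}"


@dataclass
class GeneSetCollection:
    """Named hormone-response gene sets, each tagged up or down."""

    sets: list[GeneSet]

    def __post_init__(self) -> None:
        keys = [s.key for s in self.sets]
        if len(set(keys)) != len(keys):
            raise ValueError("duplicate (hormone, direction) pairs in collection")

    def __iter__(self):
        return iter(self.sets)

    def __len__(self) -> int:
        return len(self.sets)

    @property
    def keys(self) -> list[str]:
        return [s.key for s in self.sets]

    def get(self, hormone: str, direction: str) -> GeneSet:
        for s in self.sets:
            if s.hormone == hormone and s.direction == direction:
                return s
        raise KeyError(f"no gene set for ({hormone}, {direction})")

    @classmethod
    def from_mapping(cls, mapping: Mapping[str, Sequence[str]]) -> "GeneSetCollection":
        """Build from ``{"hormone_direction": [genes]}``."""
        sets = []
        for name, genes in mapping.items():
            hormone, _, direction = name.rpartition("_")
            sets.append(GeneSet(hormone, direction, tuple(genes)))
        return cls(sets)


def read_gene_sets(path: str | Path) -> GeneSetCollection:
    """Read gene sets from GMT (set name encodes ``hormone_direction``) or
    three-column TSV (hormone, direction, gene)."""
    path = Path(path)
    if path.suffix.lower() == ".gmt":
        sets = []
        with open(path) as fh:
            for line in fh:
                parts = line.rstrip("\n").split("\t")
                if len(parts) < 3 or not parts[0]:
                    continue
                hormone, _, direction = parts[0].rpartition("_")
                genes = tuple(g for g in parts[2:] if g)
                sets.append(GeneSet(hormone, direction, genes))
        return GeneSetCollection(sets)
    df = pd.read_csv(path, sep="\t", header=None, comment="#", dtype=str)
    if df.iloc[0, 0].lower() in ("hormone",):  # tolerate a header row
        df = df.iloc[1:]
    sets = []
    for (hormone, direction), grp in df.groupby([0, 1], sort=True):
        sets.append(GeneSet(str(hormone), str(direction), tuple(grp[2])))
    return GeneSetCollection(sets)


def write_gene_sets(collection: GeneSetCollection, path: str | Path) -> Path:
    path = Path(path)
    rows = [
        {"hormone": s.hormone, "direction": s.direction, "gene": g}
        for s in collection
        for g in s.genes
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", header=False, index=False)
    return path


# ---------------------------------------------------------------------------
# CSV with provenance header
# ---------------------------------------------------------------------------

def write_csv(df: pd.DataFrame, path: str | Path, header_lines: Sequence[str] = (),
              index: bool = False) -> Path:
    """Write a CSV with ``#``-prefixed provenance comment lines on top."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        for line in header_lines:
            fh.write(f"# {line}\n")
        df.to_csv(fh, index=index)
    return path


def read_csv(path: str | Path, **kwargs) -> pd.DataFrame:
    return pd.read_csv(path, comment="#", **kwargs)
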