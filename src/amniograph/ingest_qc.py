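"""Sparse UMI matrices: 10x-style triplet I/O, QC filtering, ambient-RNA handling.

The central container is :class:`UmiCountMatrix`, a genes-by-cells sparse
integer matrix with gene identifiers, cell barcodes and per-cell metadata.
Ambient RNA is estimated with an *exclusive-marker* strategy: a set of
reporter genes (e.g. choriogonadotropin genes, which only trophoblast
transcribes) is inspected in a population known not to express them
(e.g. POU5F1-positive epiblast cells).  Any reporter UMI observed there must
be cell-free contamination, so the ratio of observed to expected-if-fully-
ambient reporter counts is a Poisson maximum-likelihood estimate of the
contaminated fraction rho of each cell's library.
"""

from __future__ import annotations

import gzip
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import scipy.sparse as sp
from scipy.io import mmread, mmwrite

__all__ = [
    "UmiCountMatrix",
    "QcThresholds",
    "AmbientEstimate",
    "read_tenx_triplet",
    "write_tenx_triplet",
    "apply_qc_filters",
    "estimate_ambient_fraction",
    "correct_ambient",
]


@dataclass
class UmiCountMatrix:
    """Genes x cells sparse matrix of nonnegative integer UMI counts.

    Parameters
    ----------
    values
        Sparse matrix, genes as rows, cells as columns.  Converted to CSR
        int64 on construction; non-integer or negative entries are rejected.
    gene_ids, barcodes
        Unique string identifiers for rows and columns.
    cell_meta
        Optional per-cell table (condition, day, batch, ...), indexed by
        barcode.  Reindexed to the barcode order of the matrix.
    """

    values: sp.spmatrix
    gene_ids: np.ndarray
    barcodes: np.ndarray
    cell_meta: pd.DataFrame = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        v = sp.csr_matrix(self.values)
        if v.dtype.kind == "f":
            if v.data.size and (np.any(v.data < 0) or np.any(v.data != np.rint(v.data))):
                raise ValueError("UMI counts must be nonnegative integers")
            v = v.astype(np.int64)
        elif v.dtype.kind in "iu":
            if v.data.size and np.any(v.data < 0):
                raise ValueError("UMI counts must be nonnegative")
            v = v.astype(np.int64)
        else:
            raise ValueError(f"unsupported count dtype {v.dtype}")
        v.eliminate_zeros()
        self.values = v
        self.gene_ids = np.asarray(self.gene_ids, dtype=str)
        self.barcodes = np.asarray(self.barcodes, dtype=str)
        if len(self.gene_ids) != v.shape[0]:
            raise ValueError(
                f"{len(self.gene_ids)} gene ids for a matrix with {v.shape[0]} rows"
            )
        if len(self.barcodes) != v.shape[1]:
            raise ValueError(
                f"{len(self.barcodes)} barcodes for a matrix with {v.shape[1]} columns"
            )
        if len(set(self.gene_ids)) != len(self.gene_ids):
            raise ValueError("gene ids are not unique")
        if len(set(self.barcodes)) != len(self.barcodes):
            raise ValueError("barcodes are not unique")
        if self.cell_meta is None:
            self.cell_meta = pd.DataFrame(index=pd.Index(self.barcodes, name="barcode"))
        else:
            missing = set(self.barcodes) - set(self.cell_meta.index.astype(str))
            if missing:
                raise ValueError(f"cell_meta lacks {len(missing)} barcodes")
            self.cell_meta = self.cell_meta.loc[self.barcodes].copy()
            self.cell_meta.index.name = "barcode"

    # -- basic geometry -------------------------------------------------
    @property
    def n_genes(self) -> int:
        return self.values.shape[0]

    @property
    def n_cells(self) -> int:
        return self.values.shape[1]

    def cell_totals(self) -> np.ndarray:
        """Total UMI per cell, N_c."""
        return np.asarray(self.values.sum(axis=0)).ravel()

    def gene_totals(self) -> np.ndarray:
        return np.asarray(self.values.sum(axis=1)).ravel()

    def genes_per_cell(self) -> np.ndarray:
        """Number of genes with at least one count, per cell."""
        return np.asarray((self.values > 0).sum(axis=0)).ravel()

    def cells_per_gene(self) -> np.ndarray:
        return np.asarray((self.values > 0).sum(axis=1)).ravel()

    # -- indexing -------------------------------------------------------
    def gene_index(self, genes: Iterable[str]) -> np.ndarray:
        lookup = {g: i for i, g in enumerate(self.gene_ids)}
        return np.array([lookup[g] for g in genes], dtype=int)

    def barcode_index(self, barcodes: Iterable[str]) -> np.ndarray:
        lookup = {b: i for i, b in enumerate(self.barcodes)}
        return np.array([lookup[b] for b in barcodes], dtype=int)

    def subset_genes(self, mask_or_idx) -> "UmiCountMatrix":
        idx = np.asarray(mask_or_idx)
        if idx.dtype == bool:
            idx = np.flatnonzero(idx)
        return UmiCountMatrix(
            self.values[idx], self.gene_ids[idx], self.barcodes, self.cell_meta
        )

    def subset_cells(self, mask_or_idx) -> "UmiCountMatrix":
        idx = np.asarray(mask_or_idx)
        if idx.dtype == bool:
            idx = np.flatnonzero(idx)
        return UmiCountMatrix(
            self.values[:, idx],
            self.gene_ids,
            self.barcodes[idx],
            self.cell_meta.iloc[idx],
        )

    def subset_cells_by_barcode(self, barcodes: Sequence[str]) -> "UmiCountMatrix":
        return self.subset_cells(self.barcode_index(barcodes))

    def copy(self) -> "UmiCountMatrix":
        return UmiCountMatrix(
            self.values.copy(), self.gene_ids.copy(), self.barcodes.copy(), self.cell_meta
        )

    def to_dense(self) -> np.ndarray:
        return np.asarray(self.values.todense())


@dataclass(frozen=True)
class QcThresholds:
    """Cell/gene filtering thresholds.

    ``max_mito_fraction`` is strict: a cell at exactly the threshold is
    dropped (the cutoff reads "mitochondrial fraction < 7.5%").
    """

    max_mito_fraction: float = 0.075
    min_cells_per_gene: int = 3
    min_genes_per_cell: int = 500

    def __post_init__(self) -> None:
        if not (0 < self.max_mito_fraction <= 1):
            raise ValueError("max_mito_fraction must be in (0, 1]")
        if self.min_cells_per_gene < 1 or self.min_genes_per_cell < 1:
            raise ValueError("count thresholds must be >= 1")


@dataclass
class AmbientEstimate:
    """Estimated contamination fraction and ambient expression profile."""

    rho: float
    ambient_profile: np.ndarray  # simplex over genes, aligned to gene_ids
    gene_ids: np.ndarray
    reporter_genes: tuple
    reporter_population: tuple
    producer_population: tuple

    def __post_init__(self) -> None:
        if not (0 <= self.rho <= 1):
            raise ValueError("rho must lie in [0, 1]")
        s = float(np.sum(self.ambient_profile))
        if abs(s - 1.0) > 1e-9:
            raise ValueError("ambient profile must sum to 1")


# ----------------------------------------------------------------------
# 10x triplet I/O
# ----------------------------------------------------------------------

def _find(dirpath: Path, stem: str) -> Path:
    for name in (stem, stem + ".gz"):
        p = dirpath / name
        if p.exists():
            return p
    raise FileNotFoundError(f"{stem}[.gz] not found in {dirpath}")


def _read_lines(path: Path) -> list[str]:
    opener = gzip.open if path.suffix == ".gz" else open
    with opener(path, "rt") as fh:
        return [line.rstrip("\n") for line in fh if line.strip()]


def read_tenx_triplet(dirpath) -> UmiCountMatrix:
    """Read a 10x-style triplet (matrix.mtx, features.tsv, barcodes.tsv).

    Files may be gzipped.  The MTX file uses 1-based coordinates with genes
    as rows.  Dimension mismatches between the MTX header and the id files
    raise ``ValueError``; a ``metadata.csv`` next to the triplet, if present,
    is attached as cell metadata.
    """
    dirpath = Path(dirpath)
    mat = mmread(str(_find(dirpath, "matrix.mtx"))).tocsr()
    features = [line.split("\t")[0] for line in _read_lines(_find(dirpath, "features.tsv"))]
    barcodes = _read_lines(_find(dirpath, "barcodes.tsv"))
    if len(features) != mat.shape[0]:
        raise ValueError(
            f"features.tsv has {len(features)} rows but matrix has {mat.shape[0]}"
        )
    if len(barcodes) != mat.shape[1]:
        raise ValueError(
            f"barcodes.tsv has {len(barcodes)} rows but matrix has {mat.shape[1]}"
        )
    meta = None
    meta_path = dirpath / "metadata.csv"
    if meta_path.exists():
        meta = pd.read_csv(meta_path, index_col=0)
        meta.index = meta.index.astype(str)
    return UmiCountMatrix(mat, np.array(features), np.array(barcodes), meta)


def write_tenx_triplet(m: UmiCountMatrix, dirpath) -> Path:
    """Write ``m`` as a canonical 10x-style triplet; returns the directory.

    Entries are emitted in column-major (CSC) order so that write -> read ->
    write is byte-identical.
    """
    dirpath = Path(dirpath)
    dirpath.mkdir(parents=True, exist_ok=True)
    coo = m.values.tocsc().tocoo()  # canonical column-major ordering
    mmwrite(str(dirpath / "matrix.mtx"), coo, field="integer")
    with open(dirpath / "features.tsv", "w") as fh:
        for g in m.gene_ids:
            fh.write(f"{g}\t{g}\tGene Expression\n")
    with open(dirpath / "barcodes.tsv", "w") as fh:
        for b in m.barcodes:
            fh.write(f"{b}\n")
    if m.cell_meta.shape[1] > 0:
        m.cell_meta.to_csv(dirpath / "metadata.csv")
    return dirpath


# ----------------------------------------------------------------------
# QC filtering
# ----------------------------------------------------------------------

def apply_qc_filters(
    m: UmiCountMatrix,
    thresholds: QcThresholds,
    mito_genes: Iterable[str],
) -> tuple[UmiCountMatrix, pd.DataFrame]:
    """Filter cells, then genes.

    Cells are dropped first, when their mitochondrial UMI fraction reaches
    ``max_mito_fraction`` (strict ``<`` retained) or when they express fewer
    than ``min_genes_per_cell`` genes.  Genes are then dropped when expressed
    (count > 0) in fewer than ``min_cells_per_gene`` of the *remaining* cells.
    Returns the filtered matrix and a per-cell QC table covering every input
    cell with a kept/dropped flag and reason.
    """
    mito_genes = list(mito_genes)
    unknown = set(mito_genes) - set(m.gene_ids)
    if unknown:
        raise ValueError(f"mito genes absent from matrix: {sorted(unknown)}")
    mito_idx = m.gene_index(mito_genes)

    totals = m.cell_totals().astype(float)
    mito_counts = np.asarray(m.values[mito_idx].sum(axis=0)).ravel() if len(mito_idx) else np.zeros(m.n_cells)
    with np.errstate(invalid="ignore", divide="ignore"):
        mito_frac = np.where(totals > 0, mito_counts / np.maximum(totals, 1), 0.0)
    n_genes_cell = m.genes_per_cell()

    high_mito = mito_frac >= thresholds.max_mito_fraction
    few_genes = n_genes_cell < thresholds.min_genes_per_cell
    keep_cell = ~(high_mito | few_genes)

    reasons = np.array(["" for _ in range(m.n_cells)], dtype=object)
    reasons[high_mito] = "mito_fraction"
    reasons[few_genes & high_mito] = "mito_fraction;few_genes"
    reasons[few_genes & ~high_mito] = "few_genes"

    qc = pd.DataFrame(
        {
            "total_umi": totals.astype(int),
            "n_genes": n_genes_cell,
            "mito_fraction": mito_frac,
            "kept": keep_cell,
            "reason": reasons,
        },
        index=pd.Index(m.barcodes, name="barcode"),
    )

    filtered = m.subset_cells(keep_cell)
    keep_gene = filtered.cells_per_gene() >= thresholds.min_cells_per_gene
    filtered = filtered.subset_genes(keep_gene)
    if filtered.n_cells == 0 or filtered.n_genes == 0:
        warnings.warn("QC filtering removed all cells or all genes", stacklevel=2)
    return filtered, qc


# ----------------------------------------------------------------------
# Ambient RNA
# ----------------------------------------------------------------------

def estimate_ambient_fraction(
    m: UmiCountMatrix,
    reporter_genes: Iterable[str],
    reporter_population: Iterable[str],
) -> AmbientEstimate:
    """Estimate the ambient contamination fraction rho via exclusive reporters.

    The ambient profile ``b_g`` is the aggregate expression profile over all
    cell-containing barcodes, normalised to a simplex.  Within the reporter
    population (cells that do not endogenously transcribe the reporters)

        rho_hat = sum_obs_reporter / sum_c N_c * sum_{g in rep} b_g,

    the maximum-likelihood ratio of observed to expected-if-fully-ambient
    reporter counts under a Poisson model, clamped to [0, 1].
    """
    reporter_genes = list(reporter_genes)
    reporter_population = list(reporter_population)
    if not reporter_population:
        raise ValueError("reporter population is empty")
    rep_gene_idx = m.gene_index(reporter_genes)
    pop_idx = m.barcode_index(reporter_population)

    gene_totals = m.gene_totals().astype(float)
    grand = gene_totals.sum()
    if grand <= 0:
        raise ValueError("matrix has no counts")
    b = gene_totals / grand
    b_rep = float(b[rep_gene_idx].sum())
    if b_rep <= 0:
        raise ValueError("reporter genes absent from the aggregate profile")

    sub = m.values[np.ix_(rep_gene_idx, pop_idx)]
    observed = float(sub.sum())
    totals_pop = m.cell_totals()[pop_idx].astype(float)
    expected_full = float(totals_pop.sum()) * b_rep
    rho = min(1.0, max(0.0, observed / expected_full)) if expected_full > 0 else 0.0

    # producers: cells whose reporter share greatly exceeds the aggregate share
    rep_counts_all = np.asarray(m.values[rep_gene_idx].sum(axis=0)).ravel()
    totals_all = np.maximum(m.cell_totals().astype(float), 1.0)
    producers = m.barcodes[rep_counts_all / totals_all > 3.0 * b_rep]

    return AmbientEstimate(
        rho=rho,
        ambient_profile=b,
        gene_ids=m.gene_ids,
        reporter_genes=tuple(reporter_genes),
        reporter_population=tuple(reporter_population),
        producer_population=tuple(producers),
    )


def correct_ambient(m: UmiCountMatrix, est: AmbientEstimate) -> UmiCountMatrix:
    """Subtract the expected ambient counts from each entry.

    x'_gc = max(0, round(x_gc - rho * N_c * b_g)), with round-half-up.
    Deterministic; corrected totals never exceed the originals and the matrix
    stays integral and nonnegative.
    """
    if est.rho == 0:
        return m.copy()
    if not np.array_equal(est.gene_ids, m.gene_ids):
        raise ValueError("ambient estimate computed on a different gene set")
    coo = m.values.tocoo()
    totals = m.cell_totals().astype(float)
    expected = est.rho * totals[coo.col] * est.ambient_profile[coo.row]
    corrected = np.maximum(0, np.floor(coo.data - expected + 0.5)).astype(np.int64)
    out = sp.coo_matrix((corrected, (coo.row, coo.col)), shape=coo.shape).tocsr()
    out.eliminate_zeros()
    return UmiCountMatrix(out, m.gene_ids, m.barcodes, m.cell_meta)
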