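"""Sparse gene-by-cell matrices and their on-disk triplet representation.

The pipeline keeps counts in genes x cells orientation throughout (rows are
genes, columns are cell barcodes), matching the 10x triplet layout on disk:
``matrix.mtx`` (Matrix Market coordinate), ``genes.tsv`` (symbol, optional
chromosome) and ``barcodes.tsv``.  All indices are 0-based in memory and
1-based only inside the MTX file, per the Matrix Market convention.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse as sp

logger = logging.getLogger(__name__)

GENOTYPES = ("control", "mutant")
TIMEPOINTS = ("E12.5", "E14.5", "E16.5", "E18.5")

CELL_TABLE_COLUMNS = [
    "barcode",
    "sample_id",
    "genotype",
    "timepoint",
    "replicate",
    "n_umis",
    "n_genes",
    "mito_frac",
    "annotation",
    "cluster",
]


class FormatError(ValueError):
    """Malformed input file (bad MTX header, mismatched dimensions, ...)."""


class AlignmentError(ValueError):
    """Gene universes of merged samples do not agree."""


@dataclass
class GeneCellMatrix:
    """A genes x cells matrix with named rows (gene symbols) and columns
    (cell barcodes).  Values may be real (e.g. counts per thousand)."""

    values: sp.csr_matrix
    gene_symbols: list[str]
    barcodes: list[str]

    def __post_init__(self) -> None:
        self.values = sp.csr_matrix(self.values)
        self.gene_symbols = list(self.gene_symbols)
        self.barcodes = list(self.barcodes)
        n_genes, n_cells = self.values.shape
        if len(self.gene_symbols) != n_genes:
            raise FormatError(
                f"{len(self.gene_symbols)} gene symbols for {n_genes} matrix rows"
            )
        if len(self.barcodes) != n_cells:
            raise FormatError(
                f"{len(self.barcodes)} barcodes for {n_cells} matrix columns"
            )
        if len(set(self.barcodes)) != n_cells:
            raise FormatError("duplicate barcodes within one matrix")
        if len(set(self.gene_symbols)) != n_genes:
            raise FormatError("duplicate gene symbols; deduplicate before building")

    @property
    def n_genes(self) -> int:
        return self.values.shape[0]

    @property
    def n_cells(self) -> int:
        return self.values.shape[1]

    def column_sums(self) -> np.ndarray:
        return np.asarray(self.values.sum(axis=0)).ravel()

    def gene_index(self, symbol: str) -> int:
        try:
            return self.gene_symbols.index(symbol)
        except ValueError:
            raise KeyError(f"gene {symbol!r} not in matrix") from None

    def subset_genes(self, symbols: list[str]) -> "GeneCellMatrix":
        idx = [self.gene_index(g) for g in symbols]
        return type(self)(self.values[idx], [self.gene_symbols[i] for i in idx], self.barcodes)

    def subset_cells(self, mask_or_idx) -> "GeneCellMatrix":
        idx = np.asarray(mask_or_idx)
        if idx.dtype == bool:
            idx = np.flatnonzero(idx)
        return type(self)(
            self.values[:, idx], self.gene_symbols, [self.barcodes[i] for i in idx]
        )


@dataclass
class CountMatrix(GeneCellMatrix):
    """Nonnegative integer UMI counts, genes x cells."""

    def __post_init__(self) -> None:
        super().__post_init__()
        if self.values.nnz:
            data = self.values.data
            if np.any(data < 0):
                raise ValueError("counts must be nonnegative")
            if not np.allclose(data, np.round(data)):
                raise ValueError("counts must be integral")
        self.values = self.values.astype(np.int64)

    def to_anndata(self):
        """Cells x genes AnnData view for interop with scanpy-style tools."""
        import anndata

        return anndata.AnnData(
            X=self.values.T.tocsr(),
            obs=pd.DataFrame(index=self.barcodes),
            var=pd.DataFrame(index=self.gene_symbols),
        )


def dedup_symbols(symbols: list[str]) -> list[str]:
    """Disambiguate duplicate gene symbols by appending ``.1``, ``.2``, ...
    in file order; deterministic."""
    seen: dict[str, int] = {}
    out = []
    for s in symbols:
        if s in seen:
            seen[s] += 1
            new = f"{s}.{seen[s]}"
            logger.warning("duplicate gene symbol %r renamed to %r", s, new)
            out.append(new)
        else:
            seen[s] = 0
            out.append(s)
    return out


def read_counts(
    matrix_path: str | Path,
    genes_path: str | Path,
    barcodes_path: str | Path,
) -> tuple[CountMatrix, dict[str, str]]:
    """Read a 10x-style triplet (MTX + genes.tsv + barcodes.tsv).

    Returns the count matrix and a gene -> chromosome map (empty strings when
    the genes file has no second column).  Duplicate gene symbols are renamed
    deterministically; duplicate barcodes within one sample are an error.
    """
    try:
        m = scipy.io.mmread(str(matrix_path))
    except Exception as exc:  # scipy raises bare ValueError on bad headers
        raise FormatError(f"cannot parse Matrix Market file {matrix_path}: {exc}") from exc
    m = sp.csr_matrix(m)

    genes = pd.read_csv(genes_path, sep="\t", header=None, dtype=str).fillna("")
    symbols = dedup_symbols(genes[0].tolist())
    chroms = genes[1].tolist() if genes.shape[1] > 1 else [""] * len(symbols)
    barcodes = pd.read_csv(barcodes_path, sep="\t", header=None, dtype=str)[0].tolist()

    if m.shape != (len(symbols), len(barcodes)):
        raise FormatError(
            f"matrix is {m.shape} but files list {len(symbols)} genes "
            f"and {len(barcodes)} barcodes"
        )
    if len(set(barcodes)) != len(barcodes):
        raise FormatError("duplicate barcodes within one sample")
    return CountMatrix(m, symbols, barcodes), dict(zip(symbols, chroms))


def write_counts(
    counts: CountMatrix,
    matrix_path: str | Path,
    genes_path: str | Path,
    barcodes_path: str | Path,
    gene_chromosomes: dict[str, str] | None = None,
) -> None:
    """Write the triplet format read back by :func:`read_counts`."""
    scipy.io.mmwrite(str(matrix_path), counts.values.tocoo(), field="integer")
    with open(genes_path, "w") as fh:
        for g in counts.gene_symbols:
            chrom = (gene_chromosomes or {}).get(g, "")
            fh.write(f"{g}\t{chrom}\n" if chrom else f"{g}\n")
    with open(barcodes_path, "w") as fh:
        fh.writelines(b + "\n" for b in counts.barcodes)


def make_cell_table(
    counts: CountMatrix,
    sample_id: str = "s1",
    genotype: str = "control",
    timepoint: str = "E12.5",
    replicate: int = 1,
    mito_prefix: str = "mt-",
) -> pd.DataFrame:
    """Per-cell metadata table aligned 1:1 with the matrix columns.

    QC metrics (n_umis, n_genes, mito_frac) are computed from the counts.
    """
    if genotype not in GENOTYPES:
        raise ValueError(f"genotype must be one of {GENOTYPES}")
    if timepoint not in TIMEPOINTS:
        raise ValueError(f"timepoint must be one of {TIMEPOINTS}")
    n_umis = counts.column_sums()
    csc = counts.values.tocsc()
    n_genes = np.diff(csc.indptr)
    mito_mask = np.array(
        [g.lower().startswith(mito_prefix.lower()) for g in counts.gene_symbols]
    )
    mito_umis = (
        np.asarray(counts.values[mito_mask].sum(axis=0)).ravel()
        if mito_mask.any()
        else np.zeros(counts.n_cells)
    )
    with np.errstate(invalid="ignore", divide="ignore"):
        mito_frac = np.where(n_umis > 0, mito_umis / np.maximum(n_umis, 1), 0.0)
    return pd.DataFrame(
        {
            "barcode": counts.barcodes,
            "sample_id": sample_id,
            "genotype": genotype,
            "timepoint": timepoint,
            "replicate": replicate,
            "n_umis": n_umis.astype(int),
            "n_genes": n_genes.astype(int),
            "mito_frac": mito_frac,
            "annotation": pd.array([None] * counts.n_cells, dtype="object"),
            "cluster": pd.array([None] * counts.n_cells, dtype="object"),
        }
    )


def merge_samples(
    samples: list[tuple[CountMatrix, pd.DataFrame]],
) -> tuple[CountMatrix, pd.DataFrame]:
    """Concatenate per-sample matrices column-wise.

    All samples must share an identical gene universe (same symbols, same
    order after harmonization).  Barcodes are suffixed ``-<sample_id>`` when
    the same barcode occurs in more than one sample, so merged barcodes stay
    unique.
    """
    if not samples:
        raise ValueError("no samples to merge")
    ref_genes = samples[0][0].gene_symbols
    for counts, _ in samples[1:]:
        if counts.gene_symbols != ref_genes:
            bad = sorted(set(counts.gene_symbols) ^ set(ref_genes))
            raise AlignmentError(f"gene universe mismatch: {bad[:10]}")

    counts_list, tables = zip(*samples)
    all_barcodes = [b for c in counts_list for b in c.barcodes]
    collide = len(set(all_barcodes)) != len(all_barcodes)

    merged_barcodes: list[str] = []
    merged_tables = []
    for counts, table in samples:
        if len(table) != counts.n_cells:
            raise FormatError("cell table does not align with matrix columns")
        sid = str(table["sample_id"].iloc[0]) if len(table) else ""
        bcs = [f"{b}-{sid}" for b in counts.barcodes] if collide else list(counts.barcodes)
        merged_barcodes.extend(bcs)
        t = table.copy()
        t["barcode"] = bcs
        merged_tables.append(t)

    merged = CountMatrix(
        sp.hstack([c.values for c in counts_list], format="csr"),
        ref_genes,
        merged_barcodes,
    )
    return merged, pd.concat(merged_tables, ignore_index=True)
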