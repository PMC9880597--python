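"""Cell-level quality control and normalization.

Filtering follows the boundary semantics of the published thresholds: cells
with *less than* ``min_umis`` UMIs or *more than* ``max_mito_frac`` of their
UMIs from mitochondrial genes are removed, so a cell sitting exactly on
either threshold is retained.  Normalization is counts per thousand (CPT):
each cell's counts scaled to sum to 1,000, optionally log1p-transformed.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
import scipy.sparse as sp

from .config import PipelineConfig
from .matrix import CountMatrix, GeneCellMatrix

logger = logging.getLogger(__name__)


def barcode_rank_inflection(
    umis_per_barcode: np.ndarray,
    fallback_threshold: float | None = None,
    smooth_window: int = 15,
) -> tuple[float, str]:
    """Locate the knee of the log-log barcode rank plot.

    Barcodes are sorted by descending UMI total; the knee is the rank
    minimizing the derivative of the rolling-median-smoothed log10(count)
    versus log10(rank) curve.  The suggested threshold is the geometric
    midpoint between the median counts of the two plateaus the knee
    separates, which keeps the rule scale-equivariant.

    Confidence is ``"low"`` when the curve is effectively unimodal: the two
    plateaus differ by less than one order of magnitude, or the knee falls
    at the extreme ranks.  On low confidence the threshold falls back to
    ``fallback_threshold`` when given.

    Returns ``(threshold, confidence)`` with confidence in {"high", "low"}.
    """
    counts = np.asarray(umis_per_barcode, dtype=float)
    counts = counts[counts > 0]
    if counts.size == 0:
        raise ValueError("all-zero barcode count vector")
    if counts.size < 10:
        raise ValueError("need at least 10 nonzero barcodes")

    counts = np.sort(counts)[::-1]
    ranks = np.arange(1, counts.size + 1)
    logc = np.log10(counts)
    logr = np.log10(ranks)

    w = min(smooth_window, counts.size)
    if w % 2 == 0:
        w -= 1
    smoothed = (
        pd.Series(logc).rolling(w, center=True, min_periods=1).median().to_numpy()
    )
    deriv = np.gradient(smoothed, logr)
    knee = int(np.argmin(deriv))

    upper = np.median(logc[: max(knee, 1)])
    lower = np.median(logc[knee:]) if knee < counts.size else logc[-1]
    separation = upper - lower
    interior = 5 <= knee <= int(0.95 * counts.size)

    threshold = float(10 ** ((upper + lower) / 2.0))
    if separation >= 1.0 and interior:
        return threshold, "high"
    logger.warning(
        "barcode rank curve looks unimodal (separation %.2f decades); "
        "knee detection is low-confidence",
        separation,
    )
    if fallback_threshold is not None:
        threshold = float(fallback_threshold)
    return threshold, "low"


def filter_cells(
    counts: CountMatrix,
    cells: pd.DataFrame,
    config: PipelineConfig | None = None,
) -> tuple[CountMatrix, pd.DataFrame]:
    """Remove cells with fewer than ``min_umis`` UMIs or more than
    ``max_mito_frac`` mitochondrial fraction; boundary values are kept.

    QC columns (n_umis, n_genes, mito_frac) are recomputed from the matrix
    so stale metadata cannot leak through the filter.
    """
    config = config or PipelineConfig()
    n_umis = counts.column_sums()
    mito_mask = np.array(
        [g.lower().startswith(config.mito_prefix.lower()) for g in counts.gene_symbols]
    )
    mito_umis = (
        np.asarray(counts.values[mito_mask].sum(axis=0)).ravel()
        if mito_mask.any()
        else np.zeros(counts.n_cells)
    )
    mito_frac = np.where(n_umis > 0, mito_umis / np.maximum(n_umis, 1), 0.0)
    keep = (n_umis >= config.min_umis) & (mito_frac <= config.max_mito_frac)

    out_counts = counts.subset_cells(keep)
    out_cells = cells.loc[np.asarray(keep)].copy().reset_index(drop=True)
    csc = out_counts.values.tocsc()
    out_cells["n_umis"] = out_counts.column_sums().astype(int)
    out_cells["n_genes"] = np.diff(csc.indptr).astype(int)
    out_cells["mito_frac"] = mito_frac[np.asarray(keep)]
    return out_counts, out_cells


def remove_sex_genes(
    counts: CountMatrix, gene_chromosomes: dict[str, str]
) -> CountMatrix:
    """Drop genes annotated to the X or Y chromosome; unmapped genes are
    retained with a warning."""
    if not gene_chromosomes:
        logger.warning("empty chromosome map; no sex genes removed")
        return counts
    unmapped = [g for g in counts.gene_symbols if g not in gene_chromosomes]
    if unmapped:
        logger.warning("%d genes lack a chromosome annotation; retained", len(unmapped))
    keep = [
        g
        for g in counts.gene_symbols
        if gene_chromosomes.get(g, "").upper() not in {"X", "Y"}
    ]
    return counts.subset_genes(keep)


def normalize_cpt(
    counts: CountMatrix,
    config: PipelineConfig | None = None,
    log1p: bool = False,
) -> GeneCellMatrix:
    """Counts per thousand: scale each cell to total ``cpt_scale`` (1,000 by
    default), optionally log1p.  The original counts object is untouched."""
    config = config or PipelineConfig()
    sums = counts.column_sums().astype(float)
    zero = np.flatnonzero(sums == 0)
    if zero.size:
        raise ValueError(
            f"cell(s) with zero total counts: {[counts.barcodes[i] for i in zero[:5]]}"
        )
    scale = sp.diags(config.cpt_scale / sums)
    cpt = (counts.values.astype(float) @ scale).tocsr()
    if log1p:
        cpt.data = np.log1p(cpt.data)
    return GeneCellMatrix(cpt, counts.gene_symbols, counts.barcodes)


def select_variable_genes(
    expression: GeneCellMatrix, n_hvg: int = 2000, n_bins: int = 20
) -> list[str]:
    """Rank genes by variance standardized against a smoothed mean-variance
    trend and return the top ``n_hvg``.

    The trend is the median variance within mean-expression quantile bins;
    a gene's score is its variance divided by the trend value at its mean.
    Constant genes score 0.  Deterministic; ties broken by gene symbol.
    """
    X = expression.values
    n_genes = X.shape[0]
    if n_genes < n_hvg:
        logger.warning("only %d genes available for n_hvg=%d", n_genes, n_hvg)
    dense = np.asarray(X.todense()) if sp.issparse(X) else np.asarray(X)
    mean = dense.mean(axis=1)
    var = dense.var(axis=1, ddof=1) if dense.shape[1] > 1 else np.zeros(n_genes)

    order = np.argsort(mean, kind="stable")
    bins = np.array_split(order, min(n_bins, n_genes))
    trend = np.ones(n_genes)
    for b in bins:
        med = np.median(var[b])
        trend[b] = med if med > 0 else 1.0
    score = var / trend

    ranked = sorted(
        range(n_genes), key=lambda i: (-score[i], expression.gene_symbols[i])
    )
    return [expression.gene_symbols[i] for i in ranked[: min(n_hvg, n_genes)]]


def qc_summary(cells: pd.DataFrame) -> dict:
    """Median/IQR summary of the per-cell QC metrics (midpoint convention
    for even n, numpy default)."""
    if len(cells) == 0:
        return {"n_cells": 0}

    def med_iqr(x):
        x = np.asarray(x, dtype=float)
        return {
            "median": float(np.median(x)),
            "iqr": [float(np.percentile(x, 25)), float(np.percentile(x, 75))],
        }

    return {
        "n_cells": int(len(cells)),
        "umis": med_iqr(cells["n_umis"]),
        "genes": med_iqr(cells["n_genes"]),
        "mito_pct": med_iqr(100.0 * cells["mito_frac"]),
    }
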