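"""Marker-anchored, semi-supervised identification of progenitor subtypes.

The approach: starting from a handful of anchor genes with known
rostro-caudal expression (Nkx2-2, Olig2, Dbx1, Rspo3), build a feature
panel from the genes most correlated and most anti-correlated with each
anchor, group the panel genes by correlation-based hierarchical clustering,
map gene groups to subpopulation labels (user-supplied, with an automatic
anchor-based suggestion), and assign each cell to the subpopulation whose
gene set carries the highest normalized total expression.

Correlations are Pearson on the log1p counts-per-thousand representation
used by the rest of the pipeline.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.cluster.hierarchy as sch
import scipy.sparse as sp
from scipy.spatial.distance import squareform
from sklearn.base import BaseEstimator, ClassifierMixin

from .matrix import GeneCellMatrix

logger = logging.getLogger(__name__)

DEFAULT_ANCHORS = ("Nkx2-2", "Olig2", "Dbx1", "Rspo3")
DEFAULT_SUBPOP_ORDER = (
    "rTh.Pro", "cTh.Pro1", "cTh.Pro2", "epiTh.Pro", "cTh.IPC", "preT.Pro",
)


@dataclass
class FeaturePanel:
    """Anchor-derived gene panel, optionally partitioned into named sets."""

    anchors: tuple[str, ...]
    panel_genes: list[str]
    correlations: pd.DataFrame = field(default_factory=pd.DataFrame)
    gene_sets: dict[str, list[str]] = field(default_factory=dict)
    subpop_order: tuple[str, ...] = DEFAULT_SUBPOP_ORDER

    def __post_init__(self) -> None:
        for label, genes in self.gene_sets.items():
            if not genes:
                raise ValueError(f"gene set {label!r} is empty")
            missing = set(genes) - set(self.panel_genes)
            if missing:
                raise ValueError(f"gene set {label!r} not within panel: {missing}")


def _dense(expression: GeneCellMatrix) -> np.ndarray:
    X = expression.values
    return np.asarray(X.todense()) if sp.issparse(X) else np.asarray(X, dtype=float)


def _pearson_vs_anchor(dense: np.ndarray, anchor_row: np.ndarray) -> np.ndarray:
    """Pearson r of every gene (row) against one anchor vector; constant
    genes get r = NaN."""
    a = anchor_row - anchor_row.mean()
    a_norm = np.linalg.norm(a)
    if a_norm == 0:
        raise ValueError("anchor gene has zero variance")
    centered = dense - dense.mean(axis=1, keepdims=True)
    norms = np.linalg.norm(centered, axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        r = centered @ a / (norms * a_norm)
    r[norms == 0] = np.nan
    return r


def anchor_correlated_features(
    expression: GeneCellMatrix,
    anchors: tuple[str, ...] = DEFAULT_ANCHORS,
    k: int = 10,
) -> FeaturePanel:
    """For each anchor take the k most-correlated and k most-anti-correlated
    genes; the panel is the deduplicated union in first-seen order.

    Each anchor is its own top positive correlate (r = 1) and hence enters
    the panel.  Ties are broken by gene symbol for determinism.
    """
    for a in anchors:
        if a not in expression.gene_symbols:
            raise KeyError(f"anchor {a!r} not in gene universe")
    dense = _dense(expression)
    symbols = expression.gene_symbols

    panel: list[str] = []
    records = []
    for anchor in anchors:
        r = _pearson_vs_anchor(dense, dense[expression.gene_index(anchor)])
        valid = np.flatnonzero(~np.isnan(r))
        by_pos = sorted(valid, key=lambda i: (-r[i], symbols[i]))
        by_neg = sorted(valid, key=lambda i: (r[i], symbols[i]))
        for direction, idx_list in (("pos", by_pos[:k]), ("neg", by_neg[:k])):
            for i in idx_list:
                records.append(
                    {"anchor": anchor, "direction": direction,
                     "gene": symbols[i], "r": float(r[i])}
                )
                if symbols[i] not in panel:
                    panel.append(symbols[i])
    return FeaturePanel(
        anchors=tuple(anchors),
        panel_genes=panel,
        correlations=pd.DataFrame(records, columns=["anchor", "direction", "gene", "r"]),
    )


def cluster_feature_genes(
    expression: GeneCellMatrix, panel: FeaturePanel, n_groups: int
) -> list[list[str]]:
    """Average-linkage agglomerative clustering of panel genes on distance
    1 - Pearson r, cut to ``n_groups``.  Constant genes are dropped with a
    warning; groups are returned with genes sorted lexicographically."""
    genes = [g for g in panel.panel_genes]
    if not genes:
        raise ValueError("empty feature panel")
    sub = expression.subset_genes(genes)
    dense = _dense(sub)
    sd = dense.std(axis=1)
    keep = sd > 0
    if not keep.all():
        dropped = [g for g, k in zip(genes, keep) if not k]
        logger.warning("dropping constant panel genes: %s", dropped)
        genes = [g for g, k in zip(genes, keep) if k]
        dense = dense[keep]
    if n_groups > len(genes):
        raise ValueError("n_groups exceeds usable panel size")
    if len(genes) == 1:
        return [genes]

    corr = np.corrcoef(dense)
    dist = 1.0 - corr
    np.fill_diagonal(dist, 0.0)
    dist = np.clip((dist + dist.T) / 2.0, 0.0, None)
    Z = sch.linkage(squareform(dist, checks=False), method="average")
    assignment = sch.fcluster(Z, t=n_groups, criterion="maxclust")
    groups: dict[int, list[str]] = {}
    for g, c in zip(genes, assignment):
        groups.setdefault(int(c), []).append(g)
    return [sorted(groups[c]) for c in sorted(groups)]


def suggest_group_labels(
    groups: list[list[str]], panel: FeaturePanel
) -> dict[str, list[str]]:
    """Name each gene group after the anchor with the highest mean positive
    correlation to the group's genes (a starting point for the manual
    group -> subpopulation mapping)."""
    if panel.correlations.empty:
        raise ValueError("panel carries no correlation table")
    rtab = panel.correlations.pivot_table(index="gene", columns="anchor", values="r")
    out: dict[str, list[str]] = {}
    for gi, genes in enumerate(groups):
        present = [g for g in genes if g in rtab.index]
        if present:
            mean_r = rtab.loc[present].mean(axis=0)
            label = str(mean_r.idxmax())
        else:
            label = f"group{gi}"
        if label in out:  # several groups may share a best anchor
            label = f"{label}.{gi}"
        out[label] = genes
    return out


def assign_cells(
    expression: GeneCellMatrix,
    gene_sets: dict[str, list[str]],
    subpop_order: tuple[str, ...] = DEFAULT_SUBPOP_ORDER,
    size_normalize: bool = True,
) -> pd.DataFrame:
    """Assign each cell to the gene set with the highest total expression.

    score(cell, s) = sum of expression over genes in s, divided by |s| when
    ``size_normalize`` (default; avoids bias toward large sets).  Exact ties
    go to the most rostral label in ``subpop_order`` and are flagged; cells
    scoring zero on every set are labeled ``"unassigned"``.
    """
    if not gene_sets:
        raise ValueError("no gene sets supplied")
    for label, genes in gene_sets.items():
        if not genes:
            raise ValueError(f"gene set {label!r} is empty")

    order = [l for l in subpop_order if l in gene_sets] + [
        l for l in gene_sets if l not in subpop_order
    ]
    dense = _dense(expression)
    row_of = {g: i for i, g in enumerate(expression.gene_symbols)}
    scores = np.zeros((len(order), expression.n_cells))
    for si, label in enumerate(order):
        rows = [row_of[g] for g in gene_sets[label] if g in row_of]
        if not rows:
            raise KeyError(f"no genes of set {label!r} present in the matrix")
        s = dense[rows].sum(axis=0)
        scores[si] = s / len(rows) if size_normalize else s

    best = np.argmax(scores, axis=0)  # first (most rostral) argmax wins ties
    top = scores[best, np.arange(scores.shape[1])]
    tie = (scores == top).sum(axis=0) > 1
    labels = np.array(order, dtype=object)[best]
    labels[top == 0] = "unassigned"
    tie[top == 0] = False

    out = pd.DataFrame({"barcode": expression.barcodes, "label": labels, "tie": tie})
    for si, label in enumerate(order):
        out[f"score_{label}"] = scores[si]
    return out


def gate_binary_marker(
    matrix: GeneCellMatrix, gene: str, threshold: float | None = None
) -> np.ndarray:
    """Per-cell boolean marker status.  With no threshold, a cell is
    positive iff its raw count is >= 1; otherwise iff its (CPT) value is
    >= threshold."""
    row = matrix.gene_index(gene)
    x = np.asarray(matrix.values[row].todense()).ravel()
    return x >= (1 if threshold is None else threshold)


class MarkerClassifier(BaseEstimator, ClassifierMixin):
    """Anchor-marker cell classifier with a scikit-learn estimator surface.

    fit() derives the feature panel from the anchors (unless explicit
    ``gene_sets`` are supplied), groups panel genes by correlation
    clustering, and maps groups to labels; predict() assigns cells by
    normalized gene-set totals.

    Parameters
    ----------
    anchors : anchor gene symbols.
    k : correlates kept per anchor and direction.
    n_groups : number of gene groups to cut the dendrogram into; defaults
        to the number of anchors.
    gene_sets : explicit label -> genes mapping; bypasses panel derivation.
    subpop_order : rostro-caudal label order used for tie-breaking.
    size_normalize : divide set scores by set size (default True).
    """

    def __init__(
        self,
        anchors: tuple[str, ...] = DEFAULT_ANCHORS,
        k: int = 10,
        n_groups: int | None = None,
        gene_sets: dict[str, list[str]] | None = None,
        subpop_order: tuple[str, ...] = DEFAULT_SUBPOP_ORDER,
        size_normalize: bool = True,
    ):
        self.anchors = anchors
        self.k = k
        self.n_groups = n_groups
        self.gene_sets = gene_sets
        self.subpop_order = subpop_order
        self.size_normalize = size_normalize

    def fit(self, expression: GeneCellMatrix, y=None) -> "MarkerClassifier":
        if self.gene_sets is not None:
            self.gene_sets_ = dict(self.gene_sets)
            self.panel_ = FeaturePanel(
                anchors=tuple(self.anchors),
                panel_genes=sorted({g for gs in self.gene_sets_.values() for g in gs}),
                gene_sets={},
                subpop_order=tuple(self.subpop_order),
            )
        else:
            self.panel_ = anchor_correlated_features(expression, tuple(self.anchors), self.k)
            n_groups = self.n_groups or len(self.anchors)
            self.gene_groups_ = cluster_feature_genes(expression, self.panel_, n_groups)
            self.gene_sets_ = suggest_group_labels(self.gene_groups_, self.panel_)
        self.classes_ = np.array(sorted(self.gene_sets_), dtype=object)
        return self

    def predict(self, expression: GeneCellMatrix) -> np.ndarray:
        table = self.predict_table(expression)
        return table["label"].to_numpy()

    def predict_table(self, expression: GeneCellMatrix) -> pd.DataFrame:
        if not hasattr(self, "gene_sets_"):
            raise RuntimeError("classifier is not fitted")
        return assign_cells(
            expression, self.gene_sets_, tuple(self.subpop_order), self.size_normalize
        )

    def score(self, expression: GeneCellMatrix, y) -> float:
        return float(np.mean(self.predict(expression) == np.asarray(y)))
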