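"""Annotation transfer across developmental time points.

Cells from all time points are embedded jointly (PCA on highly variable
genes of the log-CPT matrix), connected in a symmetrized k-nearest-neighbor
graph, and partitioned by modularity clustering.  Reference annotations
(e.g. E12.5 progenitor subtypes or E18.5 nucleus identities) then propagate
to unannotated cells through their cluster: a cluster inherits every
reference label carried by at least ``min_frac`` (default 2%) of its cells,
and may therefore carry multiple labels.

The module also implements the running-sum (Kolmogorov-Smirnov style) gene
set enrichment score used to call Shh-responsive clusters from a
fold-change-ranked gene list, with a permutation null over gene-set
membership.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import igraph as ig
import leidenalg
import numpy as np
import pandas as pd
from scipy.spatial.distance import cdist
from sklearn.base import BaseEstimator
from sklearn.decomposition import PCA
from sklearn.neighbors import NearestNeighbors

from .matrix import GeneCellMatrix

#: The nine Shh-responsive genes scored against fold-change-ranked lists.
SHH_RESPONSE_GENES = (
    "Gli1", "Ptch1", "Olig2", "Nkx2-2", "Pdlim3",
    "Fst", "Zdbf2", "Hs3st1", "Slc38a11",
)


@dataclass
class ClusterPartition:
    """A hard partition of cells with the parameters that produced it."""

    barcodes: list[str]
    membership: np.ndarray  # dense integer ids from 0
    knn_k: int
    resolution: float
    seed: int
    modularity: float

    def cluster_sizes(self) -> pd.Series:
        return pd.Series(self.membership).value_counts().sort_index()


def pca_representation(
    expression: GeneCellMatrix,
    hvg: list[str] | None = None,
    n_pcs: int = 20,
    scale: bool = True,
) -> np.ndarray:
    """Cells x n_pcs principal-component scores of the (optionally HVG-
    subset, standardized) expression matrix."""
    sub = expression.subset_genes(hvg) if hvg else expression
    X = np.asarray(sub.values.todense()).T  # cells x genes
    X = X - X.mean(axis=0)
    if scale:
        sd = X.std(axis=0)
        sd[sd == 0] = 1.0
        X = np.clip(X / sd, -10, 10)
    n_pcs = min(n_pcs, min(X.shape) - 1)
    return PCA(n_components=n_pcs, svd_solver="full").fit_transform(X)


def build_knn_graph(representation: np.ndarray, k: int) -> ig.Graph:
    """Symmetrized (union) k-nearest-neighbor graph under Euclidean
    distance.  Distance ties at the k-th neighbor are broken by cell index
    so the graph is fully deterministic."""
    X = np.asarray(representation, dtype=float)
    if not np.all(np.isfinite(X)):
        raise ValueError("representation contains non-finite values")
    n = X.shape[0]
    if k <= 0:
        raise ValueError("k must be positive")
    if k >= n:
        raise ValueError("k must be smaller than the number of cells")

    edges: set[tuple[int, int]] = set()
    if n <= 4096:
        # exact, tie-stable: lexicographic (distance, index) ordering
        D = cdist(X, X)
        np.fill_diagonal(D, np.inf)
        order = np.lexsort((np.broadcast_to(np.arange(n), (n, n)), D), axis=1)
        nn = order[:, :k]
    else:
        nbrs = NearestNeighbors(n_neighbors=k + 1).fit(X)
        idx = nbrs.kneighbors(X, return_distance=False)
        nn = np.array([row[row != i][:k] for i, row in enumerate(idx)])
    for i in range(n):
        for j in nn[i]:
            edges.add((min(i, int(j)), max(i, int(j))))
    g = ig.Graph(n=n, edges=sorted(edges), directed=False)
    return g


def cluster_cells(
    graph: ig.Graph,
    resolution: float = 1.0,
    seed: int = 0,
    barcodes: list[str] | None = None,
    knn_k: int = 0,
) -> ClusterPartition:
    """Modularity clustering of the cell graph at the given resolution.

    Uses the Leiden refinement of Louvain modularity optimization so the
    partition is deterministic under a fixed seed.
    """
    if graph.vcount() == 0:
        raise ValueError("empty graph")
    part = leidenalg.find_partition(
        graph,
        leidenalg.RBConfigurationVertexPartition,
        resolution_parameter=resolution,
        seed=seed,
    )
    membership = np.asarray(part.membership, dtype=int)
    modularity = graph.modularity(membership) if graph.ecount() else 0.0
    return ClusterPartition(
        barcodes=barcodes or [str(i) for i in range(graph.vcount())],
        membership=membership,
        knn_k=knn_k,
        resolution=resolution,
        seed=seed,
        modularity=float(modularity),
    )


def transfer_labels(
    partition: ClusterPartition,
    reference: dict[str, str],
    min_frac: float = 0.02,
) -> tuple[dict[int, list[tuple[str, float]]], dict[str, list[str]]]:
    """Attach reference labels to clusters and propagate them to cells.

    A cluster carries label L iff reference cells bearing L make up at
    least ``min_frac`` of the cluster's total cells.  Clusters may carry
    several labels (returned ordered by descending fraction, so the first
    entry is the primary label); clusters with no qualifying label are
    unlabeled (empty list).  Every cell without a reference annotation
    inherits its cluster's label list.

    Returns ``(cluster -> [(label, frac), ...], barcode -> [labels])``.
    """
    if not 0.0 < min_frac < 1.0:
        raise ValueError("min_frac must lie in (0, 1)")
    df = pd.DataFrame(
        {"barcode": partition.barcodes, "cluster": partition.membership}
    )
    df["label"] = df["barcode"].map(reference)

    cluster_labels: dict[int, list[tuple[str, float]]] = {}
    for cid, grp in df.groupby("cluster"):
        size = len(grp)
        counts = grp["label"].dropna().value_counts()
        quals = [
            (str(lab), float(cnt / size))
            for lab, cnt in counts.items()
            if cnt / size >= min_frac
        ]
        quals.sort(key=lambda t: (-t[1], t[0]))
        cluster_labels[int(cid)] = quals

    cell_labels: dict[str, list[str]] = {}
    for bc, cid, lab in zip(df["barcode"], df["cluster"], df["label"]):
        if pd.isna(lab):
            cell_labels[bc] = [l for l, _ in cluster_labels[int(cid)]]
        else:
            cell_labels[bc] = [str(lab)]
    return cluster_labels, cell_labels


def _es_from_hit_ranks(hit_ranks: np.ndarray, n_genes: int) -> np.ndarray:
    """Maximum-deviation running-sum enrichment score from sorted 1-based
    hit positions.  hit_ranks: (m, n_hits) rows of strictly increasing
    ranks.  Unweighted statistic: hits step +1/Nh, misses -1/(N-Nh)."""
    h = np.atleast_2d(hit_ranks).astype(float)
    m, nh = h.shape
    nmiss = n_genes - nh
    if nmiss <= 0:
        return np.ones(m)
    j = np.arange(1, nh + 1, dtype=float)
    peaks = j / nh - (h - j) / nmiss            # just after each hit
    troughs = (j - 1) / nh - (h - j) / nmiss    # just before each hit
    cand = np.concatenate([peaks, troughs, np.zeros((m, 1))], axis=1)
    flat_idx = np.argmax(np.abs(cand), axis=1)
    return cand[np.arange(m), flat_idx]


def shh_response_score(
    de_table: pd.DataFrame,
    panel: tuple[str, ...] = SHH_RESPONSE_GENES,
    n_permutations: int = 1000,
    seed: int = 0,
    fc_column: str = "log2_fc",
    gene_column: str = "gene",
) -> tuple[float, float]:
    """GSEA-style enrichment score of a gene panel on a fold-change-ranked
    gene list, with a permutation p-value.

    Genes are ranked by descending fold change; the running sum steps up by
    1/Nh at panel genes and down by 1/(N - Nh) otherwise, and the score is
    the maximum deviation from zero (signed; ES in [-1, 1]).  The null
    permutes panel membership over genes (``n_permutations`` draws); p is
    the one-sided fraction of permutations with ES >= observed, with the
    +1 small-sample correction.
    """
    genes = de_table[gene_column].astype(str).to_numpy()
    fc = np.asarray(de_table[fc_column], dtype=float)
    if not np.all(np.isfinite(fc)):
        raise ValueError("fold changes must be finite")
    present = [g for g in panel if g in set(genes)]
    if not present:
        raise ValueError("no panel gene present in the DE table")

    order = np.lexsort((genes, -fc))  # descending fc, symbol tie-break
    ranked = genes[order]
    n = len(ranked)
    hit_pos = np.sort(
        np.flatnonzero(np.isin(ranked, present)) + 1
    )  # 1-based ranks
    es = float(_es_from_hit_ranks(hit_pos[None, :], n)[0])

    rng = np.random.default_rng(seed)
    nh = len(hit_pos)
    u = rng.random((n_permutations, n))
    perm_ranks = np.sort(np.argpartition(u, nh - 1, axis=1)[:, :nh] + 1, axis=1)
    es_null = _es_from_hit_ranks(perm_ranks, n)
    p = float((1 + np.sum(es_null >= es)) / (n_permutations + 1))
    return es, p


class LabelTransfer(BaseEstimator):
    """Cluster-and-inherit annotation transfer with an estimator surface.

    fit(X, y): X is a cells x dims representation (e.g. PCA scores) and y
    the per-cell reference labels with None/NaN marking unannotated cells.
    predict(): the primary inherited label per cell (empty string when the
    cluster is unlabeled).
    """

    def __init__(
        self,
        knn_k: int = 15,
        resolution: float = 1.0,
        min_label_frac: float = 0.02,
        seed: int = 0,
    ):
        self.knn_k = knn_k
        self.resolution = resolution
        self.min_label_frac = min_label_frac
        self.seed = seed

    def fit(self, X: np.ndarray, y) -> "LabelTransfer":
        X = np.asarray(X, dtype=float)
        y = np.asarray(y, dtype=object)
        barcodes = [str(i) for i in range(len(y))]
        graph = build_knn_graph(X, self.knn_k)
        self.partition_ = cluster_cells(
            graph, self.resolution, self.seed, barcodes, self.knn_k
        )
        reference = {
            b: str(lab) for b, lab in zip(barcodes, y) if lab is not None and not pd.isna(lab)
        }
        self.cluster_labels_, self.cell_labels_ = transfer_labels(
            self.partition_, reference, self.min_label_frac
        )
        return self

    def predict(self, X=None) -> np.ndarray:
        if not hasattr(self, "cell_labels_"):
            raise RuntimeError("not fitted")
        out = []
        for b in self.partition_.barcodes:
            labs = self.cell_labels_[b]
            out.append(labs[0] if labs else "")
        return np.array(out, dtype=object)
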