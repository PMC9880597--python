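"""Spectral localization scores on the cell-similarity graph.

Genes marking small spatial domains of the cell graph — sub-nucleus
identities that unsupervised clustering cannot disaggregate — vary little
along edges relative to their overall variance.  The score is the
degree-normalized Rayleigh quotient of the centered expression signal on
the graph:

    R(x) = sum_{(i,j) in E} (x_i - x_j)^2  /  sum_i d_i (x_i - xbar)^2

with xbar the degree-weighted mean.  Low scores mean localized expression;
significance comes from a one-sided permutation test of the signal over
vertices.  This operates on the graph (1-skeleton) only, not on higher-
dimensional simplicial complexes.
"""

from __future__ import annotations

import logging

import igraph as ig
import numpy as np
import pandas as pd
import scipy.sparse as sp

from .matrix import GeneCellMatrix
from .stats import bh_adjust

logger = logging.getLogger(__name__)


def _graph_arrays(graph: ig.Graph) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    edges = np.array(graph.get_edgelist(), dtype=int)
    if edges.size == 0:
        raise ValueError("graph has no edges")
    degrees = np.asarray(graph.degree(), dtype=float)
    return edges[:, 0], edges[:, 1], degrees


def _rayleigh(x: np.ndarray, src, dst, deg) -> float:
    xbar = np.average(x, weights=deg)
    denom = np.sum(deg * (x - xbar) ** 2)
    if denom == 0:
        raise ValueError("constant signal: score undefined")
    num = np.sum((x[src] - x[dst]) ** 2)
    return float(num / denom)


def rayleigh_score(
    graph: ig.Graph,
    x: np.ndarray,
    n_permutations: int = 1000,
    seed: int = 0,
    _warn_disconnected: bool = True,
) -> tuple[float, float]:
    """Localization score of a per-cell signal with a permutation p-value.

    p is the one-sided fraction of vertex permutations of x whose score is
    <= the observed score (+1 correction), i.e. small p means the signal is
    more localized than chance.  A disconnected graph is scored per
    component and combined by summing numerators and denominators, with a
    warning.
    """
    x = np.asarray(x, dtype=float)
    if x.size != graph.vcount():
        raise ValueError("signal length does not match graph order")
    if _warn_disconnected and len(graph.connected_components()) > 1:
        logger.warning("graph is disconnected; score pools all components")
    src, dst, deg = _graph_arrays(graph)
    obs = _rayleigh(x, src, dst, deg)

    rng = np.random.default_rng(seed)
    null = np.empty(n_permutations)
    for i in range(n_permutations):
        null[i] = _rayleigh(rng.permutation(x), src, dst, deg)
    p = float((1 + np.sum(null <= obs)) / (n_permutations + 1))
    return obs, p


def localized_genes(
    expression: GeneCellMatrix,
    graph: ig.Graph,
    candidate_genes: list[str],
    alpha: float = 0.05,
    min_expressing_frac: float = 0.01,
    n_permutations: int = 1000,
    seed: int = 0,
) -> pd.DataFrame:
    """Rank candidate genes by localization on the cell graph.

    Candidates expressed in fewer than ``min_expressing_frac`` of cells are
    dropped; the rest are scored, BH-adjusted, and returned sorted by
    score with a significance flag at q < alpha.
    """
    X = expression.values
    dense = np.asarray(X.todense()) if sp.issparse(X) else np.asarray(X, dtype=float)
    row_of = {g: i for i, g in enumerate(expression.gene_symbols)}
    if len(graph.connected_components()) > 1:
        logger.warning("graph is disconnected; scores pool all components")

    rows = []
    for gi, gene in enumerate(candidate_genes):
        if gene not in row_of:
            continue
        x = dense[row_of[gene]]
        if np.mean(x > 0) < min_expressing_frac or np.all(x == x[0]):
            continue
        score, p = rayleigh_score(graph, x, n_permutations, seed + gi,
                                  _warn_disconnected=False)
        rows.append({"gene": gene, "score": score, "p": p})
    if not rows:
        logger.warning("no candidate gene passed the expression floor")
        return pd.DataFrame(columns=["gene", "score", "p", "q", "significant"])
    out = pd.DataFrame(rows)
    out["q"] = bh_adjust(out["p"].to_numpy())
    out["significant"] = out["q"] < alpha
    return out.sort_values("score", kind="stable").reset_index(drop=True)
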