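"""Composition enrichment, rank-based differential expression, cell-cycle
scoring, and the correlation statistics of the analysis.

Genotype-dependent depletion of a cell population is quantified by the
two-sided Fisher exact test on the 2x2 table (population membership x
genotype), oriented with control in the first column and the population in
the first row, so an odds ratio > 1 reads "depleted in the mutant".
Differential expression uses a two-sided Wilcoxon rank-sum test on CPT
values with the decision rule fold change > 2 and BH-adjusted p < 0.05;
groups larger than the subsampling cap are downsampled first.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import scipy.sparse as sp
import scipy.stats
from statsmodels.stats.multitest import multipletests

from .config import PipelineConfig
from .matrix import GeneCellMatrix


def fisher_exact_2x2(table) -> tuple[float, float]:
    """Two-sided Fisher exact test.

    Returns the sample odds ratio (a*d)/(b*c) — NaN when 0/0, +inf when
    x/0 — and the two-sided p: the total hypergeometric probability of
    tables (at fixed margins) no more likely than the observed one.
    """
    t = np.asarray(table, dtype=float)
    if t.shape != (2, 2) or np.any(t < 0):
        raise ValueError("need a nonnegative 2x2 table")
    a, b, c, d = t.ravel()
    _, p = scipy.stats.fisher_exact(t, alternative="two-sided")
    if b * c == 0:
        odds = float("nan") if a * d == 0 else float("inf")
    else:
        odds = (a * d) / (b * c)
    return float(odds), float(p)


def composition_enrichment(
    labels,
    genotype,
    label_universe: list[str] | None = None,
) -> pd.DataFrame:
    """Per-label control-vs-mutant enrichment table.

    For each label L the 2x2 table is [[a, b], [c, d]] with a = L&control,
    b = L&mutant, c = other&control, d = other&mutant; OR = ad/bc so OR > 1
    means enrichment in control (depletion in the mutant).  p-values are BH
    adjusted across labels.
    """
    labels = np.asarray(labels, dtype=object)
    genotype = np.asarray(genotype, dtype=object)
    if labels.shape != genotype.shape:
        raise ValueError("labels and genotype must align")
    present = set(np.unique(genotype))
    if not {"control", "mutant"} <= present:
        raise ValueError("both genotypes must be present")
    universe = label_universe or sorted({str(l) for l in labels})

    is_ctl = genotype == "control"
    rows = []
    for lab in universe:
        in_lab = labels == lab
        a = int(np.sum(in_lab & is_ctl))
        b = int(np.sum(in_lab & ~is_ctl))
        c = int(np.sum(~in_lab & is_ctl))
        d = int(np.sum(~in_lab & ~is_ctl))
        odds, p = fisher_exact_2x2([[a, b], [c, d]])
        rows.append({"label": lab, "a": a, "b": b, "c": c, "d": d,
                     "odds_ratio": odds, "p": p})
    out = pd.DataFrame(rows)
    out["q"] = bh_adjust(out["p"].to_numpy())
    return out


def bh_adjust(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values (monotone, order-invariant)."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1)) or not np.all(np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def _cpt_dense(expression: GeneCellMatrix) -> np.ndarray:
    X = expression.values
    return np.asarray(X.todense()) if sp.issparse(X) else np.asarray(X, dtype=float)


def de_rank_test(
    expression: GeneCellMatrix,
    group_a,
    group_b,
    config: PipelineConfig | None = None,
) -> pd.DataFrame:
    """Per-gene two-sided Wilcoxon rank-sum differential expression between
    two cell groups on CPT values.

    Groups larger than ``de_subsample`` are downsampled (seeded from the
    config) before testing.  log2 fold change is computed on group mean CPT
    with a pseudocount of 1; a gene is flagged differential iff its fold
    change exceeds ``fc_threshold`` (in either direction) and its BH q is
    below ``alpha``.  The returned frame carries the subsampled group sizes
    in ``attrs["n_used"]`` for the run report.
    """
    config = config or PipelineConfig()
    rng = np.random.default_rng(config.rng_seed)
    idx_a = _as_indices(group_a, expression)
    idx_b = _as_indices(group_b, expression)
    if idx_a.size == 0 or idx_b.size == 0:
        raise ValueError("both groups must be non-empty")
    if idx_a.size > config.de_subsample:
        idx_a = rng.choice(idx_a, config.de_subsample, replace=False)
    if idx_b.size > config.de_subsample:
        idx_b = rng.choice(idx_b, config.de_subsample, replace=False)

    dense = _cpt_dense(expression)
    A, B = dense[:, idx_a], dense[:, idx_b]
    res = scipy.stats.mannwhitneyu(A, B, axis=1, alternative="two-sided",
                                   method="asymptotic")
    p = np.asarray(res.pvalue, dtype=float)
    # constant genes: identical distributions, no evidence
    const = (A.std(axis=1) == 0) & (B.std(axis=1) == 0) & (
        A.mean(axis=1) == B.mean(axis=1)
    )
    p[const] = 1.0
    q = bh_adjust(p)
    log2_fc = np.log2((A.mean(axis=1) + 1.0) / (B.mean(axis=1) + 1.0))
    deg = (np.abs(log2_fc) > np.log2(config.fc_threshold)) & (q < config.alpha)

    out = pd.DataFrame(
        {"gene": expression.gene_symbols, "log2_fc": log2_fc,
         "p": p, "q": q, "deg": deg}
    )
    out.attrs["n_used"] = {"group_a": int(idx_a.size), "group_b": int(idx_b.size)}
    return out


def _as_indices(group, expression: GeneCellMatrix) -> np.ndarray:
    arr = np.asarray(group)
    if arr.dtype == bool:
        return np.flatnonzero(arr)
    if arr.dtype.kind in "iu":
        return arr.astype(int)
    lookup = {b: i for i, b in enumerate(expression.barcodes)}
    return np.array([lookup[b] for b in arr], dtype=int)


def cell_cycle_score(
    expression: GeneCellMatrix,
    s_genes: list[str],
    g2m_genes: list[str],
    n_bins: int = 25,
    n_controls: int = 50,
    seed: int = 0,
) -> pd.DataFrame:
    """Phase scores against expression-matched control genes.

    Each program score is the cell's mean expression over the program genes
    minus its mean over a control pool drawn (seeded) from the same
    mean-expression quantile bins — the standard background correction for
    gene-set scoring.  Phase is the argmax of (S, G2M) when positive, else
    G1.
    """
    symbols = expression.gene_symbols
    s_set = [g for g in s_genes if g in symbols]
    g2m_set = [g for g in g2m_genes if g in symbols]
    if len(s_set) < 5 or len(g2m_set) < 5:
        raise ValueError("need >= 5 genes of each program in the gene universe")

    dense = _cpt_dense(expression)
    mean_expr = dense.mean(axis=1)
    order = np.argsort(mean_expr, kind="stable")
    bin_of = np.empty(len(symbols), dtype=int)
    for b, chunk in enumerate(np.array_split(order, min(n_bins, len(symbols)))):
        bin_of[chunk] = b
    by_bin: dict[int, np.ndarray] = {
        b: np.flatnonzero(bin_of == b) for b in np.unique(bin_of)
    }
    row_of = {g: i for i, g in enumerate(symbols)}
    rng = np.random.default_rng(seed)

    def program_score(genes: list[str]) -> np.ndarray:
        rows = np.array([row_of[g] for g in genes])
        ctrl_rows = []
        for r in rows:
            pool = by_bin[bin_of[r]]
            pool = pool[pool != r]
            if pool.size == 0:
                continue
            ctrl_rows.append(rng.choice(pool, size=min(n_controls, pool.size),
                                        replace=pool.size < n_controls))
        ctrl = np.unique(np.concatenate(ctrl_rows)) if ctrl_rows else rows
        return dense[rows].mean(axis=0) - dense[ctrl].mean(axis=0)

    s_score = program_score(s_set)
    g2m_score = program_score(g2m_set)
    phase = np.where(
        (s_score <= 0) & (g2m_score <= 0),
        "G1",
        np.where(s_score >= g2m_score, "S", "G2M"),
    )
    return pd.DataFrame(
        {"barcode": expression.barcodes, "s_score": s_score,
         "g2m_score": g2m_score, "phase": phase}
    )


def g2m_shift_test(scores, genotype) -> tuple[float, float]:
    """Control-vs-mutant shift in G2/M scores.

    delta is median(mutant) - median(control); p is the two-sided Wilcoxon
    rank-sum p, exact for small tie-free samples (total n <= 50) and
    normal-approximated with tie correction otherwise.
    """
    scores = np.asarray(scores, dtype=float)
    genotype = np.asarray(genotype, dtype=object)
    ctl = scores[genotype == "control"]
    mut = scores[genotype == "mutant"]
    if ctl.size == 0 or mut.size == 0:
        raise ValueError("both genotypes must be present")
    n = ctl.size + mut.size
    ties = len(np.unique(scores)) < n
    method = "exact" if (n <= 50 and not ties) else "asymptotic"
    res = scipy.stats.mannwhitneyu(mut, ctl, alternative="two-sided", method=method)
    delta = float(np.median(mut) - np.median(ctl))
    return delta, float(res.pvalue)


def spearman(x, y) -> tuple[float, float]:
    """Spearman rank correlation with midrank ties and t-approximation p."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size or x.size < 3:
        raise ValueError("need equal-length vectors with n >= 3")
    if np.unique(x).size == 1 or np.unique(y).size == 1:
        raise ValueError("constant vector: rho undefined")
    rho, p = scipy.stats.spearmanr(x, y)
    return float(rho), float(p)
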