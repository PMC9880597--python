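"""Ground-truth scRNA-seq simulator for the developing thalamus analyses.

The generator emulates the statistical structure the pipeline assumes:

* rostro-caudally ordered progenitor domains, each defined by an anchor gene
  (Nkx2-2 for rTh.Pro, Olig2 for cTh.Pro1, Dbx1 for cTh.Pro2, Rspo3 for
  epiTh.Pro, Pax6 for preT.Pro) plus co-expressed markers whose expression
  falls off logistically with distance from the domain center, so that cells
  near soft boundaries co-express markers of adjacent domains;
* a shared G2/M cell-cycle program expressed by a fraction of cells in every
  domain, confounding progenitor structure;
* bifurcating post-mitotic lineages in which two branch markers (Sox2 and
  Foxp2 by default) rise on mutually exclusive branches along pseudotime;
* two genotypes (control, mutant) differing only by domain-specific
  depletion factors applied to the mutant's domain sampling weights;
* negative-binomial counts with a shared dispersion, lognormal library
  sizes, mitochondrial genes (``mt-`` prefixed), and an ambient-barcode
  tail for barcode-rank knee detection.

All sampling flows from a single :class:`numpy.random.Generator` seeded by
``SimulationSpec.rng_seed``, so outputs are bit-reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
import scipy.sparse as sp

from .matrix import CountMatrix, make_cell_table


class SpecError(ValueError):
    """Inconsistent simulation specification."""


G2M_PROGRAM_GENES = (
    "Mki67", "Top2a", "Ccnb1", "Cdk1", "Aurka", "Bub1", "Plk1", "Ube2c",
    "Birc5", "Cenpa", "Cenpe", "Cenpf", "Ccnb2", "Cdc20", "Aurkb", "Kif11",
    "Kif23", "Tpx2", "Hmgb2", "Nusap1",
)


@dataclass
class DomainSpec:
    """One progenitor domain along the rostro-caudal axis.

    ``position`` is the domain center on the [0, 1] axis; ``mu_high`` and
    ``mu_low`` are in-domain and background marker means on the
    counts-per-thousand scale; ``boundary_softness`` is the logistic falloff
    width of marker expression with distance from the domain (0 = hard
    indicator boundary).
    """

    name: str
    position: float
    anchor_gene: str
    marker_genes: tuple[str, ...]
    mu_high: float = 30.0
    mu_low: float = 0.5
    boundary_softness: float = 0.0

    def __post_init__(self) -> None:
        if not 0.0 <= self.position <= 1.0:
            raise SpecError("domain position must lie in [0, 1]")
        if not self.mu_high > self.mu_low >= 0.0:
            raise SpecError("require mu_high > mu_low >= 0")
        if self.boundary_softness < 0:
            raise SpecError("boundary_softness must be nonnegative")

    @property
    def genes(self) -> tuple[str, ...]:
        return (self.anchor_gene,) + tuple(self.marker_genes)


@dataclass
class LineageSpec:
    """Bifurcating post-mitotic lineage: a decaying progenitor program and
    two anti-correlated branch markers."""

    branch_markers: tuple[str, str] = ("Sox2", "Foxp2")
    branch_proportions: tuple[float, float] = (0.5, 0.5)
    progenitor_genes: tuple[str, ...] = ("Olig3", "Vim")
    pseudotime_noise: float = 0.1
    mu_high: float = 30.0
    mu_low: float = 0.01

    def __post_init__(self) -> None:
        if len(self.branch_markers) != 2 or not all(self.branch_markers):
            raise SpecError("lineage requires two branch markers")
        p = np.asarray(self.branch_proportions, dtype=float)
        if p.min() < 0 or not np.isclose(p.sum(), 1.0):
            raise SpecError("branch proportions must be nonnegative and sum to 1")


def default_domains(boundary_softness: float = 0.0) -> list[DomainSpec]:
    """Five rostro-caudal progenitor domains with anchor + five co-markers
    each; marker symbols are synthetic (``<Anchor>_co<i>``)."""
    anchors = [
        ("rTh.Pro", "Nkx2-2", 0.1),
        ("cTh.Pro1", "Olig2", 0.3),
        ("cTh.Pro2", "Dbx1", 0.5),
        ("epiTh.Pro", "Rspo3", 0.7),
        ("preT.Pro", "Pax6", 0.9),
    ]
    return [
        DomainSpec(
            name=name,
            position=pos,
            anchor_gene=anchor,
            marker_genes=tuple(f"{anchor}_co{i}" for i in range(1, 6)),
            boundary_softness=boundary_softness,
        )
        for name, anchor, pos in anchors
    ]


@dataclass
class SimulationSpec:
    """Full generative description of a synthetic dataset."""

    domains: list[DomainSpec] = field(default_factory=default_domains)
    domain_weights: tuple[float, ...] = (0.2, 0.2, 0.3, 0.2, 0.1)
    n_cells_control: int = 900
    n_cells_mutant: int = 900
    depletion: dict[str, float] = field(default_factory=dict)
    nb_dispersion: float = 2.0
    libsize_meanlog: float = float(np.log(5000.0))
    libsize_sdlog: float = 0.35
    n_housekeeping: int = 200
    housekeeping_mu: float = 4.0
    n_mito: int = 10
    mito_frac_mean: float = 0.03
    cycling_frac: float = 0.25
    g2m_genes: tuple[str, ...] = G2M_PROGRAM_GENES
    g2m_effect: float = 8.0
    g2m_baseline: float = 0.5
    lineage: LineageSpec | None = field(default_factory=LineageSpec)
    n_empty_barcodes: int = 5000
    mean_ambient_umis: float = 50.0
    rng_seed: int = 0

    def __post_init__(self) -> None:
        positions = [d.position for d in self.domains]
        if positions != sorted(positions) or len(set(positions)) != len(positions):
            raise SpecError("domain positions must be strictly increasing")
        all_markers: set[str] = set()
        for d in self.domains:
            overlap = all_markers & set(d.genes)
            if overlap:
                raise SpecError(f"marker sets overlap across domains: {sorted(overlap)}")
            all_markers |= set(d.genes)
        if len(self.domain_weights) != len(self.domains):
            raise SpecError("one weight per domain required")
        w = np.asarray(self.domain_weights, dtype=float)
        if w.min() < 0 or w.sum() <= 0:
            raise SpecError("domain weights must be nonnegative with positive sum")
        for name, f in self.depletion.items():
            if name not in {d.name for d in self.domains}:
                raise SpecError(f"depletion references unknown domain {name!r}")
            if f <= 0:
                raise SpecError("depletion factors must be positive")
        if not 0.0 <= self.cycling_frac <= 1.0:
            raise SpecError("cycling_frac must lie in [0, 1]")
        if self.nb_dispersion <= 0:
            raise SpecError("nb_dispersion must be positive")

    def gene_universe(self) -> list[str]:
        genes: list[str] = []
        for d in self.domains:
            genes.extend(d.genes)
        genes.extend(self.g2m_genes)
        if self.lineage is not None:
            for g in self.lineage.progenitor_genes + tuple(self.lineage.branch_markers):
                if g not in genes:
                    genes.append(g)
        genes.extend(f"Hk{i:04d}" for i in range(1, self.n_housekeeping + 1))
        genes.extend(f"mt-Gene{i:02d}" for i in range(1, self.n_mito + 1))
        return genes

    def control_weights(self) -> np.ndarray:
        w = np.asarray(self.domain_weights, dtype=float)
        return w / w.sum()

    def mutant_weights(self) -> np.ndarray:
        w = self.control_weights().copy()
        for i, d in enumerate(self.domains):
            w[i] *= self.depletion.get(d.name, 1.0)
        if w.sum() <= 0:
            raise SpecError("all mutant sampling weights are zero after depletion")
        return w / w.sum()


@dataclass
class SimulatedDataset:
    """Counts, per-cell metadata, and ground truth, aligned 1:1 by barcode."""

    counts: CountMatrix
    cells: pd.DataFrame
    truth: pd.DataFrame
    report: dict = field(default_factory=dict)


def analytic_odds_ratio(spec: SimulationSpec, group: set[str] | list[str]) -> float:
    """Expected control-vs-mutant odds ratio for membership in a domain
    group, computed from the sampling weights: OR = [p_c/(1-p_c)] /
    [p_m/(1-p_m)] with p the group probability per genotype."""
    group = set(group)
    idx = [i for i, d in enumerate(spec.domains) if d.name in group]
    p_c = spec.control_weights()[idx].sum()
    p_m = spec.mutant_weights()[idx].sum()
    if p_c in (0.0, 1.0) or p_m in (0.0, 1.0):
        return float("inf") if p_m in (0.0,) else float("nan")
    return float((p_c / (1 - p_c)) / (p_m / (1 - p_m)))


def _domain_activation(
    positions: np.ndarray, domain: DomainSpec, halfwidth: float
) -> np.ndarray:
    """Logistic proximity of cells to a domain; hard indicator at width 0."""
    dist = np.abs(positions - domain.position)
    if domain.boundary_softness == 0:
        return (dist <= halfwidth).astype(float)
    return 1.0 / (1.0 + np.exp((dist - halfwidth) / domain.boundary_softness))


def _halfwidth(spec: SimulationSpec) -> float:
    pos = np.array([d.position for d in spec.domains])
    gaps = np.diff(pos)
    return float(gaps.min() / 2.0) if len(gaps) else 0.5


def _nb_sample(rng: np.random.Generator, mean: np.ndarray, theta: float) -> np.ndarray:
    """NB(mean, dispersion theta): variance = mean + mean^2 / theta."""
    mean = np.asarray(mean, dtype=float)
    out = np.zeros(mean.shape, dtype=np.int64)
    pos = mean > 0
    if pos.any():
        p = theta / (theta + mean[pos])
        out[pos] = rng.negative_binomial(theta, p)
    return out


def _counts_from_relative(
    rng: np.random.Generator, rel: np.ndarray, spec: SimulationSpec, n_cells: int
) -> tuple[np.ndarray, np.ndarray]:
    """Scale relative CPT-like means by lognormal library sizes and draw NB
    counts.  Returns (counts genes x cells, library sizes)."""
    libsize = rng.lognormal(spec.libsize_meanlog, spec.libsize_sdlog, size=n_cells)
    colsum = rel.sum(axis=0)
    colsum[colsum == 0] = 1.0
    mean = rel / colsum * libsize
    return _nb_sample(rng, mean, spec.nb_dispersion), libsize


def _append_mito(rel: np.ndarray, spec: SimulationSpec) -> np.ndarray:
    """Set mitochondrial rows so the expected mito UMI share is
    mito_frac_mean."""
    if spec.n_mito == 0:
        return rel
    non_mito_total = rel[: -spec.n_mito].sum(axis=0)
    mito_total = spec.mito_frac_mean / (1 - spec.mito_frac_mean) * non_mito_total
    rel[-spec.n_mito :] = mito_total / spec.n_mito
    return rel


def _assemble(
    spec: SimulationSpec,
    rng: np.random.Generator,
    rel: np.ndarray,
    barcodes: list[str],
    truth: pd.DataFrame,
    genotype_of: np.ndarray | None = None,
    report: dict | None = None,
) -> SimulatedDataset:
    genes = spec.gene_universe()
    n_cells = rel.shape[1]
    counts_arr, _ = (
        _counts_from_relative(rng, _append_mito(rel, spec), spec, n_cells)
        if n_cells
        else (np.zeros((len(genes), 0), dtype=np.int64), np.zeros(0))
    )
    counts = CountMatrix(sp.csr_matrix(counts_arr), genes, barcodes)
    if genotype_of is None:
        cells = make_cell_table(counts, sample_id="sim", genotype="control")
    else:
        cells = make_cell_table(counts, sample_id="sim", genotype="control")
        cells["genotype"] = np.where(genotype_of, "mutant", "control")
        cells["sample_id"] = np.where(genotype_of, "sim-mut", "sim-ctl")
    truth = truth.reset_index(drop=True)
    truth.insert(0, "barcode", barcodes)
    return SimulatedDataset(counts, cells, truth, report or {})


def _progenitor_relative(
    spec: SimulationSpec,
    rng: np.random.Generator,
    domain_idx: np.ndarray,
) -> tuple[np.ndarray, pd.DataFrame]:
    """Relative (CPT-scale) mean matrix and truth for progenitor cells whose
    domain memberships are given."""
    genes = spec.gene_universe()
    gene_row = {g: i for i, g in enumerate(genes)}
    n_cells = len(domain_idx)
    rel = np.zeros((len(genes), n_cells))
    hw = _halfwidth(spec)

    centers = np.array([d.position for d in spec.domains])
    positions = rng.uniform(
        centers[domain_idx] - hw, centers[domain_idx] + hw
    ) if n_cells else np.zeros(0)

    for d in spec.domains:
        act = _domain_activation(positions, d, hw)
        mu = d.mu_low + (d.mu_high - d.mu_low) * act
        for g in d.genes:
            rel[gene_row[g]] = mu

    cycling = rng.random(n_cells) < spec.cycling_frac
    for g in spec.g2m_genes:
        rel[gene_row[g]] = spec.g2m_baseline + spec.g2m_effect * cycling

    hk_rows = [gene_row[f"Hk{i:04d}"] for i in range(1, spec.n_housekeeping + 1)]
    rel[hk_rows] = spec.housekeeping_mu

    truth = pd.DataFrame(
        {
            "domain": [spec.domains[i].name for i in domain_idx],
            "branch": "",
            "pseudotime": np.nan,
            "cycling": cycling,
        }
    )
    return rel, truth


def simulate_progenitor_field(spec: SimulationSpec) -> SimulatedDataset:
    """Single-genotype progenitor field: cells drawn across the rostro-caudal
    domains with position-graded marker expression."""
    rng = np.random.default_rng(spec.rng_seed)
    n = spec.n_cells_control
    domain_idx = rng.choice(len(spec.domains), size=n, p=spec.control_weights())
    rel, truth = _progenitor_relative(spec, rng, domain_idx)
    barcodes = [f"CELL{i:06d}" for i in range(n)]
    return _assemble(spec, rng, rel, barcodes, truth)


def simulate_genotype_pair(spec: SimulationSpec) -> SimulatedDataset:
    """Control + mutant progenitor fields; mutant cells are drawn with
    depletion-reweighted domain probabilities.  The analytic expected odds
    ratio of every domain (and of the jointly depleted group) is recorded in
    the run report."""
    rng = np.random.default_rng(spec.rng_seed)
    n_c, n_m = spec.n_cells_control, spec.n_cells_mutant
    idx_c = rng.choice(len(spec.domains), size=n_c, p=spec.control_weights())
    idx_m = rng.choice(len(spec.domains), size=n_m, p=spec.mutant_weights())
    domain_idx = np.concatenate([idx_c, idx_m])
    rel, truth = _progenitor_relative(spec, rng, domain_idx)
    genotype_of = np.concatenate([np.zeros(n_c, bool), np.ones(n_m, bool)])
    barcodes = [f"CELL{i:06d}" for i in range(n_c + n_m)]
    report = {
        "analytic_odds_ratio": {
            d.name: analytic_odds_ratio(spec, {d.name}) for d in spec.domains
        }
    }
    if spec.depletion:
        depleted = {k for k, v in spec.depletion.items() if v < 1.0}
        if depleted:
            report["analytic_odds_ratio_depleted_group"] = analytic_odds_ratio(
                spec, depleted
            )
    return _assemble(spec, rng, rel, barcodes, truth, genotype_of, report)


def simulate_lineage(spec: SimulationSpec) -> SimulatedDataset:
    """Bifurcating lineage: pseudotime t ~ U(0,1); the progenitor program
    decays in t, branch markers rise with t on their own branch only."""
    if spec.lineage is None:
        raise SpecError("lineage spec absent")
    lin = spec.lineage
    rng = np.random.default_rng(spec.rng_seed)
    n = spec.n_cells_control
    genes = spec.gene_universe()
    gene_row = {g: i for i, g in enumerate(genes)}

    t = rng.uniform(0.0, 1.0, size=n)
    branch = rng.choice(2, size=n, p=np.asarray(lin.branch_proportions, float))
    t_eff = np.clip(t + lin.pseudotime_noise * rng.normal(size=n), 0.0, 1.0)

    rel = np.zeros((len(genes), n))
    for g in lin.progenitor_genes:
        rel[gene_row[g]] = lin.mu_low + (lin.mu_high - lin.mu_low) * (1.0 - t_eff)
    for b, marker in enumerate(lin.branch_markers):
        on_branch = (branch == b).astype(float)
        rel[gene_row[marker]] = lin.mu_low + (lin.mu_high - lin.mu_low) * t_eff * on_branch

    cycling = (rng.random(n) < spec.cycling_frac) & (t < 0.5)
    for g in spec.g2m_genes:
        rel[gene_row[g]] = spec.g2m_baseline + spec.g2m_effect * cycling
    hk_rows = [gene_row[f"Hk{i:04d}"] for i in range(1, spec.n_housekeeping + 1)]
    rel[hk_rows] = spec.housekeeping_mu

    truth = pd.DataFrame(
        {
            "domain": "",
            "branch": np.array(["A", "B"])[branch],
            "pseudotime": t,
            "cycling": cycling,
        }
    )
    barcodes = [f"CELL{i:06d}" for i in range(n)]
    return _assemble(spec, rng, rel, barcodes, truth)


def simulate_barcode_ranks(spec: SimulationSpec) -> np.ndarray:
    """UMI totals over real cells plus an ambient-barcode tail.

    Real-cell totals follow the lognormal library-size model; ambient
    barcodes are Poisson at ``mean_ambient_umis``.  The returned vector is
    unsorted (real cells first, then ambient barcodes)."""
    rng = np.random.default_rng(spec.rng_seed)
    real = np.round(
        rng.lognormal(spec.libsize_meanlog, spec.libsize_sdlog, spec.n_cells_control)
    ).astype(np.int64)
    ambient = rng.poisson(spec.mean_ambient_umis, spec.n_empty_barcodes).astype(np.int64)
    return np.concatenate([real, ambient])
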