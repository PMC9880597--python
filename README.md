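# thalseq

Analysis pipeline for developmental single-cell RNA-seq of the mouse
thalamus, centered on the question of how Sonic hedgehog (Shh) signaling
from the zona limitans intrathalamica shapes the rostro-caudal array of
thalamic progenitor domains.  The package re-implements, as tested and
reusable components, the computational stages such a study needs:

* **QC and normalization** — barcode-rank knee detection, removal of cells
  with < 2,000 UMIs or > 15% mitochondrial UMIs (boundary values retained),
  X/Y gene removal, counts-per-thousand (CPT) normalization, and
  variance-trend-standardized selection of the top 2,000 variable genes.
* **Marker-anchored classification** — starting from anchor genes with
  known rostro-caudal expression (*Nkx2-2*, *Olig2*, *Dbx1*, *Rspo3*), build
  a panel of the top-k correlated and anti-correlated genes per anchor,
  group panel genes by correlation-based hierarchical clustering, and assign
  each cell to the progenitor subpopulation (rTh.Pro, cTh.Pro1, cTh.Pro2,
  epiTh.Pro, cTh.IPC, preT.Pro) whose gene set carries the highest
  size-normalized total expression.
* **Annotation transfer** — joint PCA/kNN-graph/modularity clustering of
  cells from several time points; a cluster inherits every reference label
  covering ≥ 2% of its cells, and unannotated cells inherit their cluster's
  labels.
* **Composition statistics** — per-population control-vs-mutant 2×2 tables
  with two-sided Fisher exact tests (OR = ad/bc, oriented so OR > 1 reads
  "depleted in the mutant"), BH correction, rank-sum differential
  expression with the decision rule FC > 2 and q < 0.05, cell-cycle scoring
  against expression-matched control genes, and Wilcoxon G2/M shift tests.
* **Shh-response scoring** — the running-sum (GSEA) enrichment score of the
  nine Shh-responsive genes (*Gli1, Ptch1, Olig2, Nkx2-2, Pdlim3, Fst,
  Zdbf2, Hs3st1, Slc38a11*) on a fold-change-ranked gene list, with a
  permutation null.
* **Spectral localization** — the degree-normalized Rayleigh quotient
  R(x) = Σ_{(i,j)∈E}(x_i − x_j)² / Σ_i d_i (x_i − x̄)² of a gene's
  expression on the cell kNN graph, flagging genes confined to graph
  neighborhoods that clustering cannot separate.
* **Synthetic data with ground truth** — a negative-binomial simulator of
  rostro-caudal progenitor domains with soft boundaries, a shared G2/M
  program, bifurcating *Sox2*/*Foxp2* lineages, genotype-specific domain
  depletion with known analytic odds ratios, lognormal library sizes,
  mitochondrial genes, and an ambient-barcode tail.

Everything operates on sparse gene-by-cell matrices in the 10x triplet
format (`matrix.mtx`, `genes.tsv`, `barcodes.tsv`) plus per-cell metadata
TSVs.  The classifier and the annotation transfer also expose
scikit-learn-style estimators (`MarkerClassifier`, `LabelTransfer`).

## Worked example

Simulate a control/mutant pair with 10× depletion of the two rostral
domains (analytic odds ratio exactly 10 for the depleted pair), classify
cells from their generating gene sets, and test composition:

```python
from thalseq import (SimulationSpec, simulate_genotype_pair, normalize_cpt,
                     PipelineConfig, assign_cells, composition_enrichment)

spec = SimulationSpec(
    rng_seed=0, n_cells_control=1800, n_cells_mutant=1800,
    domain_weights=(0.2, 0.2, 0.3, 0.2, 0.1),
    depletion={"rTh.Pro": 0.1, "cTh.Pro1": 0.1},
)
ds = simulate_genotype_pair(spec)
cpt = normalize_cpt(ds.counts, PipelineConfig())
sets = {d.name: list(d.genes) for d in spec.domains}
labels = assign_cells(cpt, sets)
table = composition_enrichment(labels["label"], ds.cells["genotype"].to_numpy())
print(table[["label", "a", "b", "odds_ratio", "p", "q"]].round(3).to_string(index=False))
```

prints

```
    label   a   b  odds_ratio   p   q
 cTh.Pro1 352  59       7.173 0.0 0.0
 cTh.Pro2 523 877       0.431 0.0 0.0
epiTh.Pro 379 539       0.624 0.0 0.0
 preT.Pro 182 269       0.640 0.0 0.0
  rTh.Pro 364  56       7.894 0.0 0.0
```

The two depleted domains show per-domain odds ratios near their analytic
expectation (7.2 and 7.9 individually; the grouped rTh.Pro + cTh.Pro1 test
recovers the analytic value of 10), the expanded relative share of the
other domains reads as OR < 1, and classification accuracy against the
simulator's ground truth is 1.000 on hard domain boundaries.

The same stages are available from a shell:

```sh
thalseq simulate --seed 0 --out-dir sim/ --genotype-pair
thalseq qc --in-dir sim/ --out-dir qc/
thalseq classify --in-dir sim/ --out-dir cls/
thalseq enrich --labels labels.tsv --cells sim/cells.tsv --out-dir enr/
```

## Layout

```
src/thalseq/
  matrix.py     sparse gene-by-cell containers, MTX/TSV I/O, sample merging
  config.py     pipeline thresholds (YAML-serializable)
  simulate.py   ground-truth generator
  qc.py         knee detection, filtering, CPT, variable genes
  markers.py    anchor panels, gene grouping, cell assignment
  transfer.py   kNN graph, clustering, label transfer, GSEA score
  stats.py      Fisher/BH/DE/cell-cycle/Wilcoxon/Spearman
  localize.py   graph Rayleigh-quotient localization
  cli.py        thalseq {simulate,qc,classify,transfer,enrich,score,localize}
```
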