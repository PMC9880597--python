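# Methods

## The problem and the model

The pipeline addresses a developmental question: the thalamus forms a
rostro-caudal array of neural progenitor domains, each marked by an anchor
transcription factor (*Nkx2-2* for rTh.Pro, *Olig2* for cTh.Pro1, *Dbx1*
for cTh.Pro2, *Rspo3* for epiTh.Pro), and Shh signaling from the zona
limitans intrathalamica is required to specify the rostral domains.
Comparing control embryos against mutants in which Shh enhancer activity
is removed, the analysis must (i) classify progenitors by marker panels
rather than unsupervised clustering alone, (ii) carry annotations across
developmental stages, (iii) quantify genotype-dependent changes in cell
composition, and (iv) score transcriptional response to Shh.

## Synthetic data generator

The generator produces datasets with the statistical structure those
analyses assume, plus full ground truth.  It is the substrate for every
recovery test, so its assumptions matter:

* **Domains.** Each cell belongs to one of five domains with sampling
  weights (default 0.2, 0.2, 0.3, 0.2, 0.1) and receives a rostro-caudal
  position uniform within its domain band.  A domain's anchor and five
  co-markers have expected expression `mu_low + (mu_high − mu_low)·σ((h −
  |x − p|)/w)` where p is the domain center, h the domain half-width
  (half the inter-domain spacing), and w the boundary softness; w = 0 is
  defined as the hard indicator.  Defaults `mu_high = 30`, `mu_low = 0.5`
  counts per thousand give in-domain/out-of-domain anchor ratios well
  above the 4-fold separation the classifier assumes; softness defaults
  to 0 so that tests against ground truth are exact, and is the explicit
  knob for degradation studies.
* **Counts.** Relative (CPT-scale) means are scaled per cell by a
  lognormal library size (meanlog = ln 5000, sdlog = 0.35, matching a
  realistic median of ~5,000 UMIs/cell) and sampled as negative binomial
  with a single shared dispersion θ = 2 (variance μ + μ²/θ), the simplest
  model reproducing scRNA-seq overdispersion.  200 housekeeping genes at
  4 CPT provide the inert background; 10 `mt-`-prefixed genes carry an
  expected 3% of UMIs so mitochondrial QC needs no annotation file.
* **Cell cycle.** A fraction (25%) of cells adds a flat 8-CPT increment
  on a 20-gene G2/M program — an additive program rather than a latent
  phase model, which is sufficient to create the confound that cycle
  scoring and regression must handle.
* **Lineage.** For post-mitotic analyses, pseudotime t ~ U(0,1) with a
  progenitor program decaying linearly in t and two branch markers
  (*Sox2*, *Foxp2*) rising linearly in t on mutually exclusive branches;
  branch background is 0.01 CPT so binary marker gating (count ≥ 1) has a
  low false-positive rate.  Gaussian pseudotime noise (sd 0.1) blurs the
  observed programs.
* **Genotype contrast.** Mutant cells are drawn with weights w_d·f_d
  renormalized, f the per-domain depletion factors.  The analytic odds
  ratio for any domain group, OR = [p_c/(1−p_c)]/[p_m/(1−p_m)], is
  recorded in the run report; with 10× depletion of the two rostral
  domains at the default weights it is exactly 10.  This mirrors the
  biological situation in which loss of Shh depletes rTh.Pro and cTh.Pro1.
* **Barcode tail.** Knee-detection inputs combine real-cell library sizes
  with 5,000 ambient barcodes at Poisson mean 50 UMIs.

What the generator does **not** emulate: batch effects between libraries
(so no integration step is exercised), doublets, ambient RNA
contamination of real cells, splicing dynamics, or realistic gene-gene
correlation beyond the block structure of marker programs.  Passing
recovery tests therefore demonstrates correctness of the algorithms under
the stated generative assumptions, not robustness to those artifacts.

## QC

* **Boundary semantics.** Cells are removed when UMIs are *below* 2,000
  or mitochondrial fraction is *above* 15%; cells exactly on either
  threshold are retained.
* **Knee detection.** Barcodes are sorted by descending count; the knee
  is the rank minimizing the derivative of a rolling-median-smoothed
  (window 15) log10(count) vs log10(rank) curve.  The suggested threshold
  is the geometric midpoint of the median counts of the two plateaus the
  knee separates, which makes the rule exactly scale-equivariant.
  Confidence is "low" when the plateaus differ by less than one decade or
  the knee sits in the extreme 5% of ranks; on low confidence the
  threshold falls back to the configured minimum (2,000).  Knee QC
  presumes a raw-like barcode distribution; on pre-filtered matrices the
  detector reports low confidence and the global threshold governs.
* **Variable genes.** Genes are ranked by variance divided by a
  mean-trend estimate (median variance within 20 mean-quantile bins).
  This is a deliberate, parameter-light stand-in for variance-stabilizing
  HVG selection; it is accurate when most genes in a mean range are not
  biologically variable, which holds for realistic gene universes.  On
  the compact synthetic universe (≈260 genes) the default n_hvg = 2,000
  retains all genes, which is the intended behavior.

## Marker classification

Correlation is Pearson on log1p-CPT (the representation the rest of the
pipeline uses).  Each anchor contributes its k most positive and k most
negative correlates (the anchor itself is its own top positive, r = 1);
the panel is the deduplicated union.  Panel genes are grouped by
average-linkage hierarchical clustering on 1 − r, with constant genes
dropped.  The mapping from gene groups to subpopulation names is
biological knowledge, not inferable from the data; the package therefore
takes an explicit mapping and offers an automatic suggestion that names
each group after its best-correlated anchor.  Cell assignment scores each
set by its summed CPT divided by set size — unnormalized sums would bias
toward large sets; both modes exist, size-normalized is the default.
Exact score ties go to the most rostral label and are flagged; all-zero
cells are "unassigned".

## Clustering and annotation transfer

The representation is the top 20 PCs of the standardized (clipped at
±10) HVG log-CPT matrix.  The kNN graph (k = 15, Euclidean, symmetrized
by union) breaks distance ties by cell index, making it deterministic.
Partitions optimize modularity at a configurable resolution via the
Leiden refinement of Louvain, which is seedable and deterministic; the
resolution-dependence of cluster counts is inherent and no specific count
is asserted anywhere.  A cluster inherits every reference label borne by
≥ 2% of its cells, deliberately allowing multi-label clusters;
downstream composition tests use the primary (most frequent) label.

## Enrichment score

The Shh-response score is the classic unweighted running-sum statistic:
genes ranked by descending log fold change, +1/Nh at panel genes,
−1/(N−Nh) elsewhere, score = maximum deviation (in [−1, 1]).  A
fold-change-magnitude-weighted variant is intentionally omitted from the
default because the unweighted form has the exact ±1 extremes used in
validation.  The null permutes panel membership over genes (1,000 draws),
and p is one-sided with the +1 correction, which keeps it strictly
positive and near-uniform under the null.

## Composition and differential expression

Fisher tests use the sample odds ratio ad/bc (NaN for 0/0, +∞ for x/0)
and the standard two-sided rule summing hypergeometric probabilities no
larger than the observed table's.  The orientation (control first column,
population first row) fixes OR > 1 to mean depletion in the mutant.
Adjusted p-values are Benjamini–Hochberg.

The DE routine is a two-sided Wilcoxon rank-sum test per gene on CPT with
the decision rule |FC| > 2 and q < 0.05, the fold change computed on mean
CPT with pseudocount 1.  This is a calibrated, assumption-light stand-in
for a negative-binomial GLM likelihood-ratio test; the interface accepts
externally computed per-gene tables (gene, log2_fc) wherever a ranked
list is consumed, so a GLM-based test can be plugged in without touching
the decision rule.  Groups above 2,000 cells are subsampled (seeded)
before testing and the used sizes are recorded.

Cell-cycle scores subtract the mean of a control pool drawn from
expression-matched bins (25 bins, 50 controls per program gene, seeded);
phase is the argmax of (S, G2M) when positive, else G1.  The G2/M shift
test is exact for tie-free totals ≤ 50 and normal-approximated with tie
correction otherwise; its delta is median(mutant) − median(control).

## Localization

The score is the Rayleigh quotient of the centered signal against the
graph Laplacian, normalized by degree: Σ_{(i,j)∈E}(x_i − x_j)² /
Σ_i d_i(x_i − x̄)² with x̄ the degree-weighted mean.  It is invariant to
affine transforms of x and to vertex relabeling.  The test is one-sided
(low score = localized) by permutation of the signal over vertices.  This
is the graph (1-skeleton) case of combinatorial-Laplacian localization
scoring; higher-dimensional simplicial machinery is out of scope, and the
1-skeleton suffices to rank domain-restricted genes above noise genes.

## Problem sizes and numerical choices

Recovery experiments use 400–1,800 cells per condition, 200 Monte-Carlo
seeds for odds-ratio coverage, 20 seeds per point on the
boundary-softness grid, 1,000 permutations where a BH-corrected
permutation p must be able to fall below 0.05, and 200 permutations where
only rank order matters.  These sizes put multinomial and permutation
noise well below the margins being asserted.  Monotonicity of classifier
accuracy in boundary softness is asserted up to twice the Monte-Carlo
standard error of the seed means, since the claim is about expectations.
All stochastic paths flow from explicit seeds; reruns are bit-identical.

## Known limitations

* The rank-sum DE stand-in loses power relative to count-model tests at
  small n and does not model library-size covariates beyond CPT.
* Knee detection assumes a two-plateau barcode curve; intermediate
  "shoulder" shapes yield low-confidence calls rather than a graded
  threshold.
* The HVG trend estimate degrades when a large fraction of genes in a
  mean range is biologically variable (as on very small gene universes).
* Cluster-level label transfer cannot outperform the clustering it rides
  on; heavily mixed clusters propagate multi-label sets rather than
  resolving them.
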