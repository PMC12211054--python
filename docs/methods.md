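# Methods

This note documents the models, conventions and numerical choices behind
`hepmicro`, in the order the pipeline runs them.

## Decontamination of taxonomic reports

The substrate is one record per (sample, taxon) with read count r, total
k-mer count and unique (distinct) k-mer count, as produced by k-mer
classifiers for low-biomass samples. The five filters and their
conventions:

1. **Unique k-mer floor.** A single genuine read of length L contains
   L − k + 1 distinct k-mers, so any taxon supported by real reads must
   show at least that many. Records with unique k-mers strictly below
   L − k + 1 are removed; records exactly at the threshold are retained
   ("low" reads as "below"). Defaults L = 150, k = 31 (typical short-read
   and classifier settings; both configurable).
2. **Total k-mer five-fold rule.** Genuine coverage yields many k-mer
   observations per read; records are retained only when total k-mers
   strictly exceed 5r. Equality is removed.
3. **Coherence screen.** For a genuine organism the three statistics rise
   and fall together across samples. Per taxon and per dataset (pooling
   datasets would confound depth differences), the three pairwise Spearman
   correlations are computed over the samples where the taxon occurs; the
   taxon is removed if any correlation has p ≥ α (default 0.05), is
   undefined (constant input — undefined is not significant), or the
   taxon occurs in fewer than `min_samples` (default 5, the smallest n at
   which a Spearman p < 0.05 is attainable) samples in every dataset
   (reason "insufficiency").
4. **Contaminant frequency signature.** Reagent contaminants enter at
   roughly constant mass per library, so their relative abundance falls
   as sequencing depth rises. A taxon is removed when its relative
   abundance is significantly negatively Spearman-correlated with total
   sample depth (ρ < 0, p < α). Depth is measured once, on the unfiltered
   report, and carried through the protocol — recomputing it after
   earlier filters would make the protocol non-idempotent. A reference
   contaminant profile, when supplied, removes taxa whose abundance
   profile matches it above a similarity threshold.
5. **Blacklist.** Case-insensitive exact-name matching of the taxon or any
   lineage ancestor against a reagent-contaminant genus list. The bundled
   default is a standard kitome genus list; genera with credible evidence
   as genuine hepatic residents are not on it, and studies should supply
   their own list.

Steps 1–2 act per record, steps 3–5 per taxon cohort-wide. The filter
report partitions input taxa exactly into removed (with step, reason,
offending value) and retained.

## Compositional analysis

Microbial profiles are compositions; all inference happens in log-ratio
space. CLR: x → log((x + c)/g(x + c)) per sample, with pseudocount c
defaulting to half the smallest nonzero value (0.5 for counts). Aitchison
distance is the Euclidean distance between CLR rows. Shannon diversity
H = −Σ pᵢ ln pᵢ is computed on relative abundances; a strict variant that
min-shifts and renormalizes CLR rows is available (`on_clr=True`) for
workflows phrased as "diversity of the CLR profile" — the plain CLR values
are negative and cannot enter the entropy formula directly. PCoA is
classical metric MDS (double-centring + eigendecomposition, delegated to
scikit-bio); axes with negative eigenvalues are reported but dropped.
PERMANOVA uses the standard pseudo-F from among/within sums of squared
distances with the conservative estimator p = (1 + #{F* ≥ F})/(1 + B) and
seeded label permutations. Batch removal fits, per feature, an OLS model
with sum-to-zero batch contrasts plus covariates to preserve, and
subtracts only the fitted batch component. Differential abundance is a
two-sided Wilcoxon rank-sum on CLR values versus control with BH control;
the effect size is the mean CLR difference rescaled to log2 (the canonical
compositional analogue of a fold change), and significance requires
FDR < 0.05 and |log2FC| > 1.

Rare-taxon filter: keep taxa reaching relative abundance ≥ 0.01% in ≥ 10%
of the samples of at least one dataset and detected in ≥ 2 datasets (the
multi-dataset rule relaxes automatically for single-dataset inputs).

## Host expression

Genes below the 25th variance percentile are dropped (ties at the
quantile retained). The variance-flattening transform is log2(CPM + 0.5) —
a deliberate, simple, library-normalized choice; it is pluggable.
Moderated DE fits per-gene OLS of log2 expression on a disease indicator
plus covariates. Residual variances s² (d df) are shrunk toward a scaled
inverse-chi-square prior (d₀, s₀²) fitted by the method of moments on
log s²: the excess of var(log s²) over trigamma(d/2) estimates
trigamma(d₀/2) (inverted by Newton iteration), and the prior is degenerate
(d₀ = ∞, all genes share s₀²) when no excess dispersion exists. The
moderated t uses posterior variance (d₀s₀² + d s²)/(d₀ + d) on d₀ + d df;
d₀ = 0 reproduces the ordinary t exactly (tested in closed form). DEGs:
FDR < 0.05 and |log2FC| > 1.2. Contrasts are each disease stage against
control; stages are never pooled.

Preranked GSEA: the weighted KS running sum (hits advance by |score|^w
normalized, misses retreat by 1/(N − N_h)); ES is the extremum. The null
permutes gene labels (equivalently random same-size sets) — sample labels
are already consumed by the DE model — with NES = ES / mean |null ES| of
matching sign and one-tailed p against the matching-sign null, BH across
sets. Gene sets are user-supplied GMT; no pathway database is bundled
(licensing and version drift).

## Interaction networks

Responses are genes, predictors the merged taxa matrix (CLR,
batch-corrected profiles of every rank, column-concatenated with rank
prefixes, standardized; constant columns dropped). Per gene:

- **Penalty.** λ minimizes mean leave-one-out squared prediction error on
  a 30-point log grid from λ_max = max|Xᵀ(y − ȳ)|/n down to λ_max/1000;
  ties resolve to the larger (sparser) λ. The Lasso objective is
  (1/2n)‖y − Xβ − β₀‖² + λ‖β‖₁ (scikit-learn's coordinate descent,
  tolerance 1e-7).
- **Significance.** Multi sample-splitting with 50 splits: a Lasso at the
  gene's λ selects a support on a random half; OLS on the other half
  yields p-values for the selected taxa, Bonferroni-scaled by the support
  size (p = 1 for unselected; if the support exceeds the test half's
  capacity, λ is tightened ×1.5 and the split refitted). Per taxon the
  aggregate is the scaled median min(1, 2·median), then BH across the
  gene's taxa. Reusing the full-data λ per split (rather than re-running
  CV inside each split) keeps the chain ~50× cheaper; the aggregation is
  conservative either way (verified by null calibration).
- **Stability.** 100 refits on random half subsamples with λ multiplied by
  exp(U(−0.2, 0.2)); the frequency of a nonzero coefficient must reach
  0.6. The multiplicative ±20% jitter and the 0.5 subsample fraction are
  this package's concrete choices for "random subsets with perturbed λ";
  both are parameters.
- **Edges** need FDR < 0.01 and stability ≥ 0.6; strength is Spearman ρ of
  the raw pair, and a multivariate regression on age/sex/platform
  supplies the confounder-adjusted p. FDR is controlled per gene (across
  its taxa), not across all pairs. Networks are built per stage on that
  stage's samples only; cross-stage overlap is exact (gene, taxon)
  identity.

Seeding: every gene derives child seeds from the master seed via
`SeedSequence(entropy, spawn_key=(gene_index,))`; no stage touches global
random state, and a verbatim rerun is bit-identical.

## Sparse CCA

Penalized matrix decomposition of C = ZᵀX: alternate
u ← argmax uᵀCv s.t. ‖u‖₂ ≤ 1, ‖u‖₁ ≤ c_u (soft-threshold of Cv with the
threshold found by bisection so the L1 budget binds exactly),
symmetrically for v, initialized from the leading singular vectors of C,
until the objective changes by < 1e-8. After each component C is deflated
by the rank-one term (uᵀCv)uvᵀ — deflation of the cross-product rather
than residualization keeps per-component constraints exact. Budgets
default to 0.3·√dim per side (mid-range sparsity, the primary tuning
knob); K defaults to 10 with components of |correlation| < 0.1 dropped as
degenerate; signs are fixed by making the largest-|u| entry positive;
weights below 1e-12 are zeroed so supports are exact.

PMD uses the diagonal within-block covariance approximation, so with
inactive penalties it coincides with classical (whitened) CCA only when
within-block covariance is near-diagonal; the oracle-equivalence test
uses diagonally coupled data for that reason. Cluster membership is the
nonzero (or floor-exceeding) support; cluster genes are annotated by the
upper-tail hypergeometric test against a user universe, BH within
cluster, FDR < 0.05.

## Single-cell co-localization

Cells with ≥ 1 decontaminated microbial read are microbe-carrying.
Per-cell-type carriage enrichment: Fisher exact on (type vs rest) ×
(carrying vs not) within each condition, BH across types. Active
interaction cells for a cluster: expression strictly above ("exceeds")
the gene's q-quantile (default q = 0.75, linear-interpolation quantiles)
for ≥ 1 cluster gene AND reads strictly above the taxon's q-quantile for
≥ 1 cluster taxon; quantiles are computed within condition over all cells
(not only carriers — a documented choice, configurable through the
condition argument). Strictness implies: a gene expressed in ≤ 25% of
cells has a zero 75th percentile, so any positive count passes on the
gene side; and an active cell is always microbe-carrying.

## Synthetic cohorts

The generator emulates a multi-dataset liver RNA-seq study: four stages,
datasets as batches, and the four input kinds. What it models — and what
it does not — determines what passing tests show about real data:

- **Taxon reports.** Genuine taxa: log-normal reads scaled by a
  log-normal per-sample depth; total k-mers ≈ r(L − k + 1)·U(0.9, 1),
  unique k-mers ≈ r(L − k + 1)·U(0.85, 0.95) capped by a genome capacity
  — tight monotone coupling to reads, as the coherence screen assumes.
  Contaminant classes are planted one rule each (distinct-k-mer
  saturation; totals in (2r, 4.8r); unique counts independent of reads;
  blacklisted genus with otherwise genuine statistics), with read floors
  chosen so each class fails *only* its own rule — that separability is
  what makes per-step recall measurable, and it is idealized: real
  contaminants violate several rules at once.
- **Expression.** Negative binomial (size 20) around a log-normal
  baseline; DE genes shift by ±2 log2 units in every disease stage;
  per-(dataset, gene) batch shifts N(0, 0.5) on the log2 scale.
- **Taxa.** Dirichlet-multinomial (concentration 80) with ±2.5 log2
  concentration shifts for differential taxa. No phylogenetic
  correlation, no zero-inflation beyond the multinomial's.
- **Couplings.** Planted gene log2 expression = baseline + 0.8·CLR(taxon)
  + N(0, 0.3); the distilled stage generator plants the same linear model
  on standardized Gaussian predictors (n = 80, 100 genes, 60 taxa, 10
  edges). Real effect sizes are unknown; these values define the regime
  in which the chain's recall ≥ 0.8 / FDR ≤ 0.1 guarantees are
  demonstrated.
- **Single cell.** Poisson UMI with block-signature cell types; carriage
  fraction 0.3 concentrated 4:1 in one cell type; planted active cells
  boosted above the cluster thresholds.

Null-calibration fixtures use n = 25 per group for the rank-sum test: at
smaller n the discreteness of the rank-sum distribution (plus the
continuity correction) makes a KS-against-uniform check reject for a
non-negligible fraction of seeds even though the test is exactly valid;
n = 25 is inside the asymptotic regime the check presumes.

## Problem sizes and runtime

Default verification scales: decontamination 30 samples × 200 taxa; DE
2,000 genes × 60 samples/contrast; interaction chain 100 genes × 60 taxa
× 80 samples (≈ 70 s single-threaded — the dominant cost, ~230 small
Lasso fits per gene); CCA and single-cell fixtures run in seconds. The
end-to-end driver caps the interaction scan at the top `max_genes_interact`
DE-ranked genes per stage (default 30); genome-wide scans are a direct
library call on the same functions.

## Known limitations

- The coherence screen needs ≥ 5 occurrences per dataset; rare genuine
  taxa are removed as "insufficiency" by design.
- Multi sample-splitting p-values are conservative; power at n < 40 per
  stage is limited.
- PMD sparse CCA maximizes covariance, not whitened correlation; reported
  canonical correlations are computed post hoc from the fitted scores.
- The GSEA null (gene permutation) understates inter-gene correlation;
  sample-permutation nulls are out of scope.
- No phylogenetic diversity, rarefaction, strain resolution, or pathway
  database retrieval.
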