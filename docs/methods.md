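# Methods

`engramsig` re-implements, as a tested library, the analysis chain by which
activity-induced transcriptional programs are identified in single
hippocampal nuclei and used to predict which dentate granule (DG) neurons
will reactivate on re-exposure to an environment. This note documents the
models, the parameters that matter, the synthetic-data generator that
stands in for sequencing data, and the numerical choices made where the
design was genuinely open.

## Data model

Expression is a genes × nuclei matrix of log2(TPM+1) values held as a
pandas DataFrame with unique gene and nucleus identifiers (TPM =
transcripts per million). Per-nucleus metadata carries the behavioural
condition (HC home cage; NE1h/NE4h/NE5h single novel-environment exposure
sampled 1/4/5 h later; AA/AC double exposure to the same or a different
environment), the sorted population (DG, CA1, VIP, …), FOS and ARC protein
status from flow cytometry, mouse, batch, total aligned reads and detected
genes. On-disk formats are dense TSV or MatrixMarket coordinate files with
sidecar gene/nucleus name lists; TSV is written at full precision
(`%.17g`) so round trips are exact.

## Quality control

Two nucleus filters:

- **Depth** — drop nuclei with total aligned reads < 100,000 or detected
  genes < 4,000 (boundary values pass). These defaults are calibrated to
  real SmartSeq2-scale data; on a simulated transcriptome of *G* genes the
  detected-gene cutoff is rescaled to *G*/4 and the Arc threshold below is
  shifted by log2(20,000/*G*), because TPM mass concentrates on fewer
  genes.
- **Arc concordance** — drop nuclei sorted as FOS-protein-negative whose
  Arc mRNA exceeds 2.5 log2(TPM+1) (strict inequality): these were likely
  active shortly before sacrifice with FOS protein already decayed, so they
  contaminate the inactive baseline. The rule never touches FOS+ nuclei,
  and the pipeline exempts nuclei collected through an ARC+ gate — for
  those, FOS−/Arc-high is the collection criterion, not an inconsistency.

Both filters are idempotent and commute. The original study additionally
removed clustering-based extreme outliers without publishing a rule;
`exclude_cluster_outliers` offers a conservative silhouette-based stand-in,
off by default.

## Differential expression

The two-group statistic is a reproducibility-optimized regularized
difference of means,

    d_g = |m_A,g − m_B,g| / (alpha1 + alpha2 · s_g),

with s_g the pooled standard error. The pair (alpha1, alpha2) is selected
from alpha1 ∈ {0, 0.1, …, 5} × alpha2 ∈ {0, 1} by maximizing a
standardized reproducibility score: B bootstrap datasets (default 500,
resampling nuclei within groups) are formed into pairs, the mean overlap of
their top-K gene lists is compared with the same quantity under
group-label permutation, and Z = (R_K − R0_K)/sd(R0_K) is maximized over
the grid and over K ∈ {25, 50, 100, 250, 500}. With alpha2 = 0 the
ranking is alpha1-invariant (pure fold change), so that branch is
evaluated once.

Significance is by group-label permutation of the selected statistic with
the null **pooled across genes**: each permuted dataset contributes its
full vector of null statistics. Pooling is what makes small p-values
resolvable at snRNA-seq group sizes (a per-gene null with 20+20 nuclei and
1,000 permutations could never reach the Benjamini–Hochberg thresholds
that 2,000 genes require); the statistic is standardized by its standard
error precisely so that pooling across genes is coherent. When the number
of distinct label assignments C(n, n_A) is at most 200 the enumeration is
exhaustive (including the observed assignment, so p ≥ 1/(#assignments ×
#genes) and the p-values match a brute-force oracle exactly); otherwise
1,000 Monte-Carlo permutations with an add-one correction are used.
Zero-variance genes are safe at alpha1 = 0: d is +∞ when the means differ
and 0 when they do not. FDR control is Benjamini–Hochberg.

The size-matched comparison across cell types subsamples each population
to 10 FOS+ and 10 FOS− nuclei without replacement, repeats 5 times,
counts FDR < 0.05 genes per repetition, and compares counts across
populations with a one-way ANOVA (SD reported as NaN for a single
repetition).

## Cell-type identification

Hierarchical iterative clustering: (1) embed the nuclei with t-SNE
(initial PCA to 20 dimensions, perplexity 17, exact gradient for theta =
0, seeded); (2) bisect the 2-D embedding by complete-linkage hierarchical
clustering (Euclidean, k = 2); (3) test the bisection by the
differential-expression contract above (a reduced bootstrap count, B =
100, keeps deep recursions affordable); (4) accept the split only if at
least `min_de_genes` (default 10) genes pass FDR < 0.05 and both branches
have at least `min_leaf` (default 10) nuclei; (5) recurse. Perplexity is
reduced to (n−1)/3 on small branches so the embedding stays defined.
Leaves partition the input; the tree records each split's supporting
genes. Prior-knowledge labelling maps each leaf to the cell-type whose
marker genes are most highly expressed in it (`name_clusters`); in the
pipeline this merges activity sub-states of one population (e.g. FOS+ and
FOS− DG, which separate strongly in the embedding) into one cell type
before refinement. The pipeline runs cell typing on the home-cage and 1-h
strata, the conditions the procedure is designed for.

Refinement fits a random forest on genes with ≥ 10 TPM summed over all
nuclei, keeps genes with Mean-Decrease-Gini > 1, refits, applies the
cutoff again, and uses the surviving set to re-predict every nucleus's
label out-of-bag. Per-cluster precision is the fraction of the cluster's
nuclei recovered out-of-bag. Mean-Decrease-Gini is computed on the
conventional unnormalized scale (raw impurity decrease weighted by in-bag
counts, averaged over trees) because the published cutoffs (> 1 here,
> 0.4 below) are stated on that scale; scikit-learn's normalized
`feature_importances_` would make them meaningless.

## Temporal signatures

Three comparisons against HC FOS− (1 h FOS+, 4 h ARC+FOS−, 5 h
ARC+FOS−) define a significance pattern per gene at adjusted p < 0.05.
The seven non-empty patterns map to groups: {1h}→1, {5h}→2, {4h}→3,
{4h,5h}→4, {1h,4h,5h}→5, {1h,5h}→6, {1h,4h}→7. The early signature is
group 1, sustained group 5, late group 4. Group 7 is the one subset the
original group list leaves unnamed; assigning it {1h,4h} completes the
enumeration.

The late-signature score is the projection of each nucleus on PC1 of the
late genes (PCA on centered, unscaled log2(TPM+1)); the sign is oriented
so nuclei with high summed late-gene expression score positive, making the
score comparable across runs. Labels: the default `two_means` policy
splits scores by 1-D 2-means and calls the higher-center cluster late,
flagging a warning when the center separation is below the pooled
within-cluster SD (or when all scores are equal); the `fixed(t)` policy is
available with the boundary assigned to late (the published threshold of
10 is in dataset-specific units and does not transfer across scalings,
hence the data-driven default). Double-exposure ARC+FOS+ nuclei labelled
early become **NewlyActivated**, late become **Reactivated**;
double-exposure ARC+FOS− nuclei are **NotReactivated**.

Pseudotime restricts the matrix to activity genes, reduces to a
2-component subspace, and rotates the axes to independence with FastICA.
The trajectory metric keeps the variance-preserving subspace scale — the
rotation does not change distances, whereas unit-variance whitening would
inflate the noise axis to the signal's scale and scramble the spanning
tree. A minimum spanning tree is built over nuclei in component space and
pseudotime is the geodesic distance from one end of the tree's diameter
path, with the root chosen so pseudotime increases with the anchor gene
(Arc by default; if the anchor is absent or constant, summed
activity-gene expression is used and flagged). Group differences are
Student's t-tests on pseudotime. Branch-point detection is out of scope;
only the 1-D activity ordering is preserved, and recovery is validated by
planted-order rank correlation rather than by matching any particular
trajectory tool.

## Reactivity prediction

Candidate predictive genes are the Reactivated-vs-NotReactivated DEGs
(FDR < 0.05) filtered for expression consistency: upregulated genes must
be expressed above 1 log2(TPM+1) in ≥ 80% of Reactivated nuclei,
downregulated genes in ≤ 40%. Genes differentially expressed at 1 h vs HC
(immediate-early artefacts) or associated with batch are excluded; batch
association is a Kruskal–Wallis test across batches at FDR < 0.05 (the
original criterion is unstated). The selection is order-invariant and
idempotent.

An initial feature-elimination round fits one forest on the three-class
training problem and keeps genes with Mean-Decrease-Gini above the pooling
cutoff (0.4). The three-way fit is the right one to eliminate with: it
concentrates importance on genes separating *any* pair of classes, so both
the on/off predictive genes (which separate Reactivated from everything)
and the graded late-program genes (which separate NotReactivated from
NewlyActivated) survive. An iterative backward elimination was evaluated
and rejected: with cleanly separable training classes the out-of-bag error
is zero at every set size, so error-based selection degenerates to the
smallest set and discards the redundancy that stabilizes the
probabilities. If nothing clears the cutoff the candidate set passes
through unchanged.

Training draws 15 nuclei per class (NewlyActivated, NotReactivated,
Reactivated); the remainder is the held-out test set, disjoint by
construction. Two pairwise forests are fit — model i (Reactivated vs
NewlyActivated) and model ii (Reactivated vs NotReactivated) — genes with
Mean-Decrease-Gini > 0.4 in either are pooled, and a three-way forest on
the pooled genes yields per-class hold-out errors, ROC curves
(trapezoidal AUC over probability thresholds) and reactivation
probabilities. The default forest size is 10,000 trees in the pipeline;
the test suite and acceptance script use 1,000, which changes only the
Monte-Carlo noise of the vote fractions. Applied to single-exposure 4/5-h
nuclei, the three-way model calls a nucleus predicted-Reactivated (pR)
when its most probable class is Reactivated, else pNR.

Validation uses the **reactivity component**: among the first 10 principal
components of the full transcriptome, the one maximizing the absolute
two-sample t-statistic between reactivity-defined subgroups (FOS+ nuclei
split by early/late signature, or late-signature nuclei split by FOS
status). The component sign is fixed by `positive_group` so the
reactivated-side group scores higher (PCA signs being arbitrary), and the
Pearson correlation between component scores and predicted probabilities
is tested — including on a second, independently sampled cohort scored by
the first cohort's model.

## Functional enrichment and GO distance

Enrichment is an upper-tail hypergeometric test of a gene set against each
annotation term within a stated universe, BH-corrected across the tested
terms (by default terms with overlap ≥ 1, the common enrichment
convention). The gene–gene distance represents each gene as an indicator
vector over its terms scaled by w_t = log2(1 + parent_count_t) — deeper,
more specific terms weigh more; the formula is this package's choice, with
identity weighting available — and takes 1 − cosine similarity. The
distance is symmetric, zero on identical annotation sets, 1 on disjoint
ones, and invariant to rescaling all weights. Networks are exported as a
tab-separated edge list of pairs at or below a distance threshold.
Annotations are flat (gene, term) and (term, parent_count) tables; full
ontology parsing is out of scope, and a parent-count table derived from a
real ontology can be supplied externally.

## Synthetic cohorts

The generator draws counts per gene × nucleus from a negative binomial
(variance = μ + φμ², dispersion φ = 0.3 by default; φ = 0 gives
Poisson), applies expression-dependent dropout, converts to TPM per
nucleus and then log2(TPM+1). Structure:

- **Cell types** — DG, CA1 and VIP by default, each with
  `marker_genes_per_type` = 30 markers elevated by
  `marker_effect_size` = 3 log2 units. Identity separation deliberately
  exceeds the activity `effect_size` = 2, as in real data where cell type
  dominates the transcriptome.
- **Temporal groups** — gene counts default to 252/129/107 for the
  early/late/sustained groups (the reported sizes) and 20 for each minor
  group. A gene with pattern S is shifted (up for 80% of genes, down for
  the rest) in any nucleus whose activity profile intersects S: early
  nuclei are {1h}; late nuclei {4h} or {5h} by condition (double-exposure
  late nuclei are {5h}, being 5 h past the first exposure); Reactivated
  nuclei {1h, 5h}. Only the configured responsive population (DG) shifts;
  other cell types are transcriptional nulls for activity.
- **Reactivated late boost** — sustained/late genes gain a further +1
  log2 in Reactivated nuclei, reflecting the renewed late program after a
  second activation. This graded difference is what makes some non-IEG
  genes differ between Reactivated and NotReactivated, which the
  predictive-gene workflow presupposes.
- **Predictive genes** — 60 genes, off at μ = 0.1 and on at μ = 25
  counts, carried by Reactivated nuclei and by a `reactivated_fraction`
  (0.41, matching the class proportions used for training/testing) of
  single-exposure 4/5-h late nuclei ("primed"). Each gene is on in a
  carrier nucleus only with probability 0.9 (and on spuriously with 0.05
  elsewhere): no single gene separates the classes, mirroring the
  observation that reactivity is predicted by a coordinated set rather
  than any one transcript. This penetrance also produces the bimodal
  expression of predictive genes across single-exposure nuclei.
- **Library ballast** — 100 housekeeping-like genes at μ ∈ [500, 2000]
  carry most of the library mass. Without them, asymmetric induction
  inflates the library and shifts every null gene on the TPM scale (the
  compositional artefact of relative measures), making generator truth
  ill-defined for error-rate scoring; with realistic ballast the artefact
  is damped to well below detection thresholds.
- **Dropout** — Bernoulli zeroing after the count draw with rate
  `dropout_rate · exp(−μ/dropout_decay)` (0.2 and 10 by default): lowly
  expressed transcripts drop out often, deeply covered ones almost never,
  as in deep-coverage SmartSeq2 nuclei. A flat rate would zero
  high-expression genes at the same rate, which real protocols do not.
- **Batch and metadata** — per-(gene, batch) shifts N(0, 0.15 log2) over 2
  batches; mice assigned 3 per condition; total aligned reads = 10 ×
  library counts; detected genes = genes above 1 log2(TPM+1). Arc's
  baseline mean is pinned low (μ = 1), which is the premise of the
  Arc-concordance rule.
- **Gene seed** — gene-level biology (roles, directions, baseline
  abundances) derives from `gene_seed` (default: the main seed), so a
  second independent cohort simulated with the same `gene_seed` shares
  gene identities while resampling animals, batches and nuclei.

Default nucleus counts mirror the study design: 88 double-exposure
ARC+FOS+ and 65 ARC+FOS− DG nuclei in A>A (yielding roughly 15 training +
37/50/21-sized test classes), 30 per single-exposure stratum, 40 home-cage
DG, and 15-nucleus strata for CA1 and VIP. Everything is drawn from
`numpy.random.default_rng(seed)`, so identical configuration and seed
reproduce the cohort bit for bit.

**What passing tests do and do not show.** The generator emulates marker
structure, temporal programs, priming, batch shifts, dropout and
library-size variation, but its genes are conditionally independent given
the planted structure — there are no co-regulated modules beyond the
planted ones, no ambient contamination, no doublets, no gene-length or
GC effects, and cell types are equidistant. Recovery results on synthetic
cohorts therefore demonstrate that the implementation does what it claims
under the stated model, not that the biological conclusions would
replicate on new sequencing data.

## Problem sizes and reproducibility

The test suite and acceptance script run every stage at reduced but
non-trivial scale, chosen so the full suite completes on a single CPU in
well under half an hour: differential expression at 2,000 genes × 40
nuclei with B = 500 bootstraps; subsampling at 3 populations × 5
repetitions; clustering at 150 nuclei; the reactivity stage on the full
463-nucleus default cohort with 1,000-tree forests; and the end-to-end
pipeline twice at default scale for the byte-identity check. All stage
seeds derive from a single seed via `numpy.random.SeedSequence`, and
pipeline outputs are written with fixed float formatting so reruns are
byte-identical (timestamps live only in the manifest).

## Known limitations

- Permutation p-values are pooled across genes; genes with pathological
  (heavy-tailed) noise could distort the shared null. The standardized
  statistic mitigates this but does not remove it.
- The bisection tests splits with the same data used to propose them, so
  the per-split FDR is optimistic ("double dipping"); the stopping rule
  (≥ 10 genes at FDR < 0.05) absorbs small excesses, and final clusters
  are validated independently by out-of-bag precision.
- The fixed late-signature threshold (10) is not portable across data
  scalings; `two_means` is the default for that reason, and it assumes a
  genuinely bimodal score.
- Mean-Decrease-Gini cutoffs (1 and 0.4) are scale-dependent: importance
  dilutes as the number of redundant informative features grows, which is
  why the elimination step precedes pooling.
- The reactivity component searches only the first 10 principal
  components; a reactivity axis below that rank would be missed.
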