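# engramsig

Activity-induced transcriptional signatures and engram-reactivation
prediction from single-nucleus RNA-seq.

When a mouse explores a novel environment, a sparse set of dentate granule
(DG) neurons activates, and a subset of those neurons — putative engram
cells — reactivates when the animal re-encounters the same environment.
Flow cytometry can separate recently active nuclei by immediate-early-gene
protein status (FOS decays within hours; ARC persists ~5 h in DG), but
protein status alone cannot tell a *Reactivated* nucleus (active in both
exposures) from a *NewlyActivated* one (active only in the second).
`engramsig` implements the transcriptomic workflow that makes that
distinction and then predicts, from a single exposure, which neurons are
primed to reactivate:

- **Synthetic cohorts** with full ground truth (negative-binomial counts →
  TPM → log2(TPM+1); cell-type markers, temporal gene groups, batch
  effects, expression-dependent dropout, and a partially penetrant
  predictive-gene program), so every stage is testable without sequencing
  data.
- **Quality control**: read/gene-count depth filters and the
  Arc-concordance rule (FOS⁻ nuclei with Arc mRNA > 2.5 log2(TPM+1) are
  excluded from the inactive baseline).
- **Cell typing**: hierarchical iterative clustering — t-SNE embedding,
  complete-linkage bisection, each split validated by differential
  expression, recursion until splits can no longer support it — followed
  by random-forest refinement with out-of-bag per-cluster precision.
- **Differential expression**: a reproducibility-optimized statistic
  d = |m_A − m_B| / (α₁ + α₂·s), with (α₁, α₂) tuned by bootstrap
  top-list reproducibility against a permuted-label null, permutation
  p-values (exhaustive on small groups) and Benjamini–Hochberg FDR;
  plus the size-matched subsampling comparison across cell types and
  exact hypergeometric set-overlap tests.
- **Temporal signatures**: genes grouped 1–7 by their significance pattern
  across the 1 h / 4 h / 5 h comparisons against home cage (early = 1 h
  only; sustained = all three; late = 4 h + 5 h only); per-nucleus
  late-signature scores from PC1 of the late genes; early/late labels;
  NewlyActivated / NotReactivated / Reactivated classes; MST-based
  activity pseudotime.
- **Reactivity prediction**: predictive-gene selection (expression in
  ≥ 80% of Reactivated nuclei for upregulated genes, ≤ 40% for
  downregulated, at a 1 log2(TPM+1) cutoff; immediate-early and
  batch-associated genes excluded), pairwise random forests with
  Mean-Decrease-Gini pooling (> 0.4) into a three-way classifier,
  ROC/AUC on held-out nuclei, primed-state (pR/pNR) prediction for
  single-exposure 4–5 h nuclei, and validation against the "reactivity
  component" of the transcriptome on an independent cohort.
- **GO tools**: local hypergeometric enrichment and a weighted-cosine
  gene–gene distance over GO annotations (terms weighted by parent
  count), with network export.

## Worked example

`examples/07_reactivity_prediction.py` runs the reactivity stage on a
default simulated double-exposure cohort (463 nuclei, 2,000 genes):

```
reactivity classes: {'NotReactivated': 65, 'NewlyActivated': 49, 'Reactivated': 39}
156 putative predictive genes after all filters
held-out per-class error: {'NewlyActivated': 0.0, 'NotReactivated': 0.02, 'Reactivated': 0.0}
model i (R vs NA): AUC = 1.000
model ii (R vs NR): AUC = 1.000

single-exposure 4/5-h nuclei called pR: 41.7% (planted primed fraction 41.7%);
recall of planted primed nuclei: 100.0%
```

Reading this: from the Reactivated-vs-NotReactivated DEGs, 156 genes
survive the consistency and exclusion filters; forests trained on 15
nuclei per class classify the held-out nuclei with ≤ 2% error per class
and separate Reactivated nuclei from either alternative with AUC 1.0 on
this synthetic cohort; applied to nuclei collected 4–5 h after a *single*
exposure, the model calls 41.7% predicted-Reactivated (pR), recovering
every nucleus the simulation primed — i.e. the signature that predicts
reactivation is already present hours before a second exposure.

The other scripts in `examples/` each demonstrate one capability
(simulation, QC, cell typing, differential expression, temporal
signatures, pseudotime, GO networks, and the full pipeline). The pipeline
is also available from the shell:

```bash
engramsig pipeline --out run1 --seed 1234   # simulate → QC → ... → GO network
engramsig simulate --out cohort --seed 7    # just the synthetic cohort
engramsig de --matrix m.tsv --group-a a.txt --group-b b.txt --out de.tsv
```

Identical configuration and seed reproduce every stage output byte for
byte. See `docs/methods.md` for the models, parameter defaults and their
rationale, and the generator's scope and limitations.

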