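"""Reproducibility-optimized differential expression between activated
(FOS+) and inactive (FOS-) dentate granule nuclei.

The statistic d = |mean difference| / (alpha1 + alpha2 * SE) has its
regularization tuned by maximizing bootstrap top-list reproducibility
against a permuted-label null; significance is by label permutation with
Benjamini-Hochberg FDR control.
"""

from engramsig import ROTSParams, SimulationConfig, overlap_test, rots_test, simulate_experiment

matrix, metadata, truth = simulate_experiment(SimulationConfig(seed=2))
dg = metadata[metadata["population"] == "DG"]
fos_pos = list(dg.index[(dg["condition"] == "NE1h") & (dg["fos_protein"] == "pos")])
hc = list(dg.index[(dg["condition"] == "HC") & (dg["fos_protein"] == "neg")])

result = rots_test(matrix[fos_pos], matrix[hc], ROTSParams(B=500, seed=1234))
sig = result[result["p_adj"] < 0.05]
print(f"selected alpha1={result.attrs['alpha1']}, alpha2={result.attrs['alpha2']}, "
      f"top-list size K={result.attrs['K']}")
print(f"{len(sig)} of {len(result)} genes differentially expressed at FDR < 0.05")

truth_early = set(truth.gene_truth.index[
    truth.gene_truth["temporal_group"].isin([1, 5, 6, 7])])
hits = set(sig.index)
print(f"sensitivity vs planted activity genes: "
      f"{len(hits & truth_early) / len(truth_early):.2f}; "
      f"false discoveries: {len(hits - truth_early)}")

p = overlap_test(hits, truth_early, set(result.index))
print(f"hypergeometric p of the overlap with the planted set: {p:.2e} "
      "(tiny, as it must be when the test recovers the planted program)")
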