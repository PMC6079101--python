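"""Apply the nucleus-level quality filters to a simulated cohort.

Two rules: a depth filter (minimum aligned reads and detected genes; values
below the cutoff fail, boundary values pass) and the Arc-concordance rule
(FOS-protein-negative nuclei with high Arc mRNA were likely active recently
and are excluded from the inactive baseline).
"""

from engramsig import (
    SimulationConfig,
    exclude_arc_discordant,
    qc_filter_nuclei,
    simulate_experiment,
)

matrix, metadata, _ = simulate_experiment(SimulationConfig(seed=1))

# thresholds scaled to the simulated transcriptome (2,000 genes rather than
# the ~20,000 of a real run, so absolute cutoffs shift accordingly)
depth = qc_filter_nuclei(matrix, metadata, min_reads=100_000, min_genes=500)
print("depth filter:", depth.summary())

candidates = [n for n in depth.retained_ids
              if metadata.loc[n, "arc_protein"] != "pos"]
arc = exclude_arc_discordant(matrix[candidates], metadata, arc_threshold=5.8)
print("Arc-concordance filter:", arc.summary())
print(f"\n{arc.n_fail_arc_rule} FOS- nuclei had Arc mRNA above threshold. "
      "Any such nucleus is dropped: it was probably active shortly before "
      "sacrifice even though FOS protein had already decayed.")
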