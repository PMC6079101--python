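"""Order nuclei along an activity-state trajectory.

Expression of activity-responsive genes is reduced to two independent
components; a minimum spanning tree over nuclei defines a trajectory and
pseudotime is the geodesic distance from one end of its diameter path,
oriented so Arc expression increases along it.
"""

from scipy.stats import spearmanr

from engramsig import SimulationConfig, activity_pseudotime, simulate_experiment

matrix, metadata, truth = simulate_experiment(SimulationConfig(seed=5))
dg = metadata[metadata["population"] == "DG"]
keep = dg.index[dg["condition"].isin(["HC", "NE1h"])]
m = matrix[list(keep)]

activity_genes = list(truth.gene_truth.index[
    truth.gene_truth["temporal_group"].isin([1, 5])])
states = truth.nucleus_truth.loc[keep, "activity_state"]

pt, tests, flags = activity_pseudotime(m, activity_genes, seed=1,
                                       groups=states)
print(f"pseudotime computed for {len(pt)} nuclei "
      f"(anchor fallback: {flags['anchor_fallback']})")
print("\ngroup comparisons (Student's t):")
print(tests.to_string(index=False))

rank_sep = pt[states == "early"].mean() - pt[states == "baseline"].mean()
rho = spearmanr(pt.to_numpy(),
                (states == "early").astype(int).to_numpy()).statistic
print(f"\nearly nuclei sit {rank_sep:.2f} pseudotime units above baseline "
      f"(rank correlation with activity state: {rho:.2f}); the trajectory "
      "recovers the planted activity axis.")
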