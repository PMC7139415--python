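"""Stratify samples by their dependency on EGF+bFGF (E&F).

Samples are Ward-clustered on their raw growth-index profiles; each cluster
is labeled E&F-dependent when its members gain substantially and
significantly from adding E&F to the same factor combinations, else
E&F-independent.  IDH1-mutant samples should concentrate in the
independent group (tested with Fisher's exact test).
"""

from gfscan import (
    build_index_matrix,
    enumerate_conditions,
    generate_cohort,
    group_enrichment,
    hierarchical_cluster,
    label_clusters,
    simulate_readouts,
)

catalog = enumerate_conditions()
cohort = generate_cohort(seed=0)
gim = build_index_matrix(simulate_readouts(cohort, catalog, seed=0), catalog)

assignment = label_clusters(hierarchical_cluster(gim, k=4), gim.index, catalog)
labels = assignment.sample_ef_label
print("cluster sizes and E&F labels:")
for cid, label in sorted(assignment.ef_labels.items()):
    n = int((assignment.clusters == cid).sum())
    print(f"  cluster {cid}: n={n:2d}  {label}")

truth_match = (labels == cohort["true_ef_group"]).mean()
print(f"\nagreement with the simulator's planted groups: {truth_match:.1%}")

table, odds, p = group_enrichment(labels, cohort, "idh1_mut")
frac = table.loc["independent", True] / table[True].sum()
print(f"\nIDH1-mut samples in the E&F-independent group: {frac:.0%} "
      f"(Fisher two-sided p = {p:.4f})")
print("a small p with most mutants independent mirrors the biology that "
      "IDH1-mutant stem cells grow poorly under conventional E&F media")
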