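"""Rank conditions by growth success rate within genotype subgroups.

The growth success rate of a condition is the fraction of samples whose
six-day growth rate D6/D0 strictly exceeds 1.  Ranking it per genotype
subgroup nominates tailored culture media: the simulator plants PEDF+MDK
synergy in mesenchymal IDH1-wild-type cells, PlGF+IL-6 in 1p19q-intact
IDH1-mutants and PEDF+SHH in co-deleted IDH1-mutants.
"""

from gfscan import (
    build_index_matrix,
    enumerate_conditions,
    generate_cohort,
    rank_conditions,
    simulate_readouts,
)

catalog = enumerate_conditions()
cohort = generate_cohort(seed=0)
gim = build_index_matrix(simulate_readouts(cohort, catalog, seed=0), catalog)

subgroups = {
    "mesenchymal IDH1-wt": (~cohort.idh1_mut) & (cohort.true_subtype == "mesenchymal"),
    "IDH1-mut, 1p19q intact": cohort.idh1_mut & ~cohort.codel_1p19q,
    "IDH1-mut, 1p19q co-deleted": cohort.idh1_mut & cohort.codel_1p19q,
}

for name, mask in subgroups.items():
    ranking = rank_conditions(gim, cohort.index[mask])
    top = ranking.iloc[0]
    print(f"{name} (n={int(mask.sum())}):")
    print(f"  top condition: {ranking.index[0]}")
    print(f"  success rate {top['success_rate']:.2f} over {int(top['n_evaluable'])} samples, "
          f"mean index {top['mean_index']:.2f}, "
          f"{top['fold_vs_reference']:.1f}x the NBE mean index")
print("each subgroup's winner is the pair+E&F condition whose synergy the "
      "generator planted for that genotype")
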