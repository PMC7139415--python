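"""Screen every (mutation, condition) pair for growth associations.

For each annotated driver gene and each condition, the difference in mean
cell growth index between mutant and wild-type samples is tested with a
two-sided Wilcoxon rank-sum test; Benjamini-Hochberg q-values accompany the
raw p-values.  The output table maps directly onto a volcano plot (x =
delta, y = -log10 p).
"""

import numpy as np

from gfscan import (
    build_index_matrix,
    enumerate_conditions,
    generate_cohort,
    mutation_condition_screen,
    simulate_readouts,
)

catalog = enumerate_conditions()
cohort = generate_cohort(seed=0)
gim = build_index_matrix(simulate_readouts(cohort, catalog, seed=0), catalog)

# within IDH1-mutant samples, which conditions favor ATRX-mutant growth?
idh1_mut = cohort.index[cohort.idh1_mut]
screen = mutation_condition_screen(gim, cohort, ["atrx_mut"], restrict=idh1_mut)
screen["neglog10p"] = -np.log10(screen["p"])
top = screen.nsmallest(5, "p")

print(f"tested {len(screen)} (gene, condition) pairs among {len(idh1_mut)} "
      f"IDH1-mutant samples\n")
print("strongest ATRX associations:")
for _, row in top.iterrows():
    print(f"  {row.condition_id:<18s} delta={row.delta:+.2f}  "
          f"p={row.p:.2e}  q={row.q:.2e}")
tgfb_top = top["condition_id"].str.contains("TGF-β").any()
print(f"\nTGF-β-containing condition among the top hits: {tgfb_top}")
print("the simulator plants a TGF-β growth boost in ATRX-mutant IDH1-mutant "
      "cells, mirroring TGF-β pathway enrichment in ATRX-mutant astrocytomas")
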