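"""Enumerate the growth-factor condition catalog and its plate layout.

The screen tests every single candidate growth factor and every unordered
pair, each with and without the basal EGF+bFGF supplement (E&F), plus two
controls (factor-free basal media and NBE = basal media with E&F alone).
"""

from gfscan import enumerate_conditions, plate_layout

catalog = enumerate_conditions()
pairs_no_ef = [c for c in catalog.non_control if c.kind == "pair" and not c.with_ef]
singles = [c for c in catalog.non_control if c.kind == "single"]

print(f"total conditions (incl. 2 controls): {len(catalog)}")
print(f"non-control conditions:              {len(catalog.non_control)}")
print(f"two-factor mixtures without E&F:     {len(pairs_no_ef)}")
print(f"single-factor conditions (+/- E&F):  {len(singles)}")
print(f"with/without-E&F twin pairs:         {len(catalog.ef_pairing)}")
print(f"example labels: {catalog.labels[2:5]} ... {catalog.labels[-1]}")

layout = plate_layout(catalog, n_replicates=2)
print(f"\n384-well layout in technical duplicates: {len(layout)} wells "
      f"on {layout['plate'].nunique()} plate(s); first well {layout.iloc[0]['well']}")
# 11 candidate factors -> 55 pairs + 11 singles, each +/- E&F = 132
# conditions; with both controls in duplicate the screen fits one plate.
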