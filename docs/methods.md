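# Methods

## Screen design

A screening panel has two basal factors (EGF and bFGF, jointly E&F, 5
ng/mL) and *m* candidate growth factors (default panel: 11 glioma-associated
factors at 1 ng/mL). The catalog contains every single candidate and every
unordered candidate pair, each with and without E&F — `2·(C(m,2) + m)`
non-control conditions, 132 for m = 11 — plus two controls: factor-free
basal media (`NO_GF`) and basal media with E&F alone (`NBE`). Condition
labels list factors in case-insensitive alphabetical order with an `/E&F`
suffix (`MDK/PEDF/E&F`); labels parse back to equal conditions, and ASCII
aliases (`TGFB`, `IL6`, `PLGF`, ...) are accepted on input. Plate layout is
deterministic row-major fill with replicates adjacent; no claim is made
about the physical well map of any real screen, and edge effects are out of
scope. Concentrations are metadata only.

## Screen statistics

Each well is read as ATP luminescence at seeding (D0) and day 6 (D6); each
sample additionally has a day-6 factor-free series (N6, carried under the
`NO_GF` condition id). The cell growth index is `G = (D6 − N6)/D0` and the
growth rate `R = D6/D0`.

**QC.** A replicate passes iff D6 > `min_signal` (default 5000 counts) and
D6/D0 > `min_ratio` (default 0.5), both strict inequalities. The signal
rule is applied to the day-6 readout — the quantity that reflects viable
cells after culture; the two timepoints are not symmetric and the seeding
signal is already controlled by design (1000 cells/well). N6 wells are
averaged at face value rather than QC-filtered: they measure basal
survival, which is exactly what the viability rule is built to reject, so
filtering them would bias the background upward.

**Aggregation.** Replicate luminescence is averaged per role *before*
applying the index formula; N6 is a per-sample scalar, so role-level
averaging is the only consistent choice. If one duplicate fails QC the
surviving replicate is used (replicate counts are recorded); cells with no
surviving replicate, and all cells of a sample with no N6 series, are
masked (NaN in both `index` and `rate`).

**Derived statistics.** Replicate concordance between two profiles of the
same sample is the squared Pearson correlation over shared unmasked
conditions (≥ 3 required). Group growth comparisons use the two-tailed
Welch t-test. The growth success rate of a condition is the fraction of
evaluable samples with R > 1 (strict); masked samples leave both numerator
and denominator.

## E&F-dependency stratification

Samples are clustered on their raw growth-index rows (no scaling — the
index is already a per-sample-normalized quantity) with Ward linkage and
Euclidean distance, and the tree is cut at k clusters (default 4). Masked
cells are imputed with the sample's row mean solely for the distance
computation (logged). The implementation is `scipy.cluster.hierarchy`; an
exhaustive-merge re-implementation that recomputes every pairwise Ward cost
at each step serves as the test oracle for n ≤ 12.

Each cluster is labeled **E&F-dependent** iff a two-tailed paired t-test of
its members' mean index over the 66 with-E&F conditions versus the 66
matched without-E&F conditions gives p < `alpha` (default 0.05) *and* the
mean difference exceeds `min_delta` (default 0.25 index units); otherwise
**independent**. The effect-size floor is deliberate: significance alone
tests whether *any* E&F benefit exists, and in a cluster of 15–40 samples
even a biologically trivial but consistent benefit (a few percent of the
index scale) reaches p < alpha. Dependence is a statement about magnitude,
so the rule pairs significance with an effect threshold, exactly as
p-plus-fold-change rules do in differential expression. The floor of 0.25
index units sits an order of magnitude below the with-E&F gains of truly
dependent samples (≈ 1–2 index units in both the simulator and published
screens of this design) and an order of magnitude above assay-level
variation of the paired contrast. Singleton clusters are labeled by their
single delta against the same floor, with a warning.

Genotype enrichment between the dependent/independent labels and any
annotation flag uses the two-sided Fisher exact test, with the 2×2 table
returned for reporting.

## Condition ranking and mutation associations

Within a sample subgroup, conditions are ranked by growth success rate,
with ties broken by subgroup mean index, then canonical label. The
fold-change versus the NBE reference is the ratio of subgroup mean indices
over samples evaluable in both conditions (a ratio of means, not a mean of
per-sample ratios — the latter explodes whenever a sample's reference index
is near zero, which is common for cells that do not respond to E&F); a zero
reference mean yields a missing fold, not an error.

The mutation–condition screen tests, per annotated gene and condition, the
difference in index between mutant and wild-type samples with the
two-sided Wilcoxon rank-sum test: the exact null distribution when both
groups have ≤ 10 observations and the pooled values are tie-free, the
normal approximation with tie correction otherwise. Pairs where either
group has fewer than two evaluable samples are skipped. Raw p-values are
reported (they are what a volcano plot shows) with Benjamini–Hochberg
q-values alongside across all emitted pairs, so the screen is honest about
multiplicity without hiding the per-test evidence.

## Transcriptome procedures

Expression is handled as genes × samples log2(RPKM+1) matrices.

**Tumor-intrinsic filter.** Stem-cell cultures lose microenvironment cells,
so classification uses only genes conserved between cultures and parental
tissues: Spearman ρ ≥ 0.4 (inclusive) across ≥ 5 sample pairs, annotated,
and expressed (value > 0) in at least half of tissues *and* half of
cultures. The zero rule is evaluated as a per-gene zero fraction in each
matrix; genes whose zero fraction exceeds one half in either are dropped.
A per-gene report records ρ, zero fractions and the drop reason.

**Differential expression.** Per-gene two-tailed Welch t-test with BH
q-values; a gene is differential iff p ≤ 0.05 and q ≤ 0.1 (defaults).
Genes constant in both groups get p = 1. This is a deliberate stand-in for
count-model DEG methods: the pipeline holds log-RPKM summaries, not read
counts, so a normal-theory test at the same thresholds is the appropriate
tool at this data level.

**Nearest-template prediction.** Marker genes (disjoint lists per class,
≥ 10 present per class) are z-standardized gene-wise across samples. Each
class template is +1 on its own markers and −1 on the other classes'; a
sample is assigned the class minimizing the cosine distance
`1 − cos(sample, template)`. Significance is the add-one fraction of
`n_perm` random equal-sized gene sets achieving a distance at most as small
(so the smallest attainable p is `1/(n_perm+1)`), with BH q across samples.
Samples missing more than half the markers are classified but flagged
low-confidence; exact distance ties fall back to class-name order with a
tie flag. Predictions are invariant to gene order and per-gene affine
rescaling (absorbed by the standardization).

**ssGSEA.** Per sample, genes are ranked by expression descending (top gene
carries rank value N) and the score is the sum over the ranking of the
difference between the in-set ECDF weighted by `rank^0.25` and the uniform
out-of-set ECDF. Scores are rank-based and therefore invariant to strictly
increasing per-sample transforms. For subtype assignment each set's scores
are z-normalized across samples and each sample takes the argmax set, with
ties flagged; a zero-variance score row normalizes to zeros.

**Two-class GSEA.** Genes are ranked by signal-to-noise
`(μ_a − μ_b)/(σ_a + σ_b)`; the enrichment score is the extremum of the
running sum weighted by `|metric|` (exponent 1). The null is `n_perm`
random gene sets of equal size — gene-set permutation, not phenotype
permutation, which is the better-powered choice for a single small cohort.
NES is ES over the mean |null ES| of matching sign, and p (= FDR for a
single set) is the add-one same-signed tail fraction.

Subtype gene sets and dependency templates are ordinary GMT files; the
simulator's `subtype_templates` provides synthetic marker sets for testing,
and real marker lists are user-supplied, never vendored.

## The synthetic cohort model

`generate_cohort` draws 72 samples (19 LGG, 53 glioblastoma by default) at
the composition of the published screen cohort: every LGG IDH1-mutant,
9/19 LGGs 1p19q-co-deleted, 6/53 glioblastomas IDH1-mutant, ATRX mutation
mutually exclusive with co-deletion, transcriptional subtype only for
IDH1-wild-type glioblastomas (proneural/classical/mesenchymal at
11/19/16 ÷ 46), and a latent E&F-dependency group: IDH1-mutants are
independent with probability 0.72, IDH1-wild-types by subtype (proneural
0.18, classical 0.47, mesenchymal 0.56). All frequencies are exposed in
`CohortFrequencies` and validated against [0, 1].

**Growth model.** Per-day log-growth of sample *i* under condition *c* is

```
r(i, c) = b_i + Σ_{f∈c} [β(f) + jitter_i(f)] + synergy(pair(c), g_i) + E&F(i, c)
```

with D6 = D0·exp(6·r) and N6 = D0·exp(6·b_i) before noise. Readout noise
is multiplicative log-normal per well (σ = 0.05, a typical technical CV
for ATP-luminescence assays; it reproduces the near-0.99 replicate R² such
platforms report). Baselines b_i are uniform on (−0.08, −0.02)/day: cells
decline slowly in factor-free basal media — if baselines were positive,
every condition would trivially "succeed" and the success-rate statistic
could not discriminate. The 2–9-day doubling times reported for these
cultures are realized under the strongest planted conditions
(r ≈ 0.08–0.31/day). Baseline and response jitter are derived from a
stable hash of the sample id, not the run seed, so re-simulating a sample
under a new seed reproduces its growth profile up to measurement noise —
mirroring a re-screen of an independently thawed vial.

Planted effects (defaults): each candidate factor adds 0.01/day (± 0.01
sample-specific jitter); each basal factor adds 0.09/day in dependent
samples and 0.01/day in independent ones — independence is relative, not
absolute, which is also what makes the pair+E&F winners separable from
their E&F-free twins in subgroups that happen to contain no dependent
member; TGF-β adds a further 0.08/day in ATRX-mutant IDH1-mutant samples;
and three genotype-specific pair synergies add 0.15/day: PEDF+MDK in
mesenchymal IDH1-wild-types, PlGF+IL-6 in 1p19q-intact IDH1-mutants,
PEDF+SHH in co-deleted IDH1-mutants.

**What the simulator does not emulate.** Plate spatial artifacts,
mechanistic signaling, cell-cycle structure, and the magnitude of
NBE-relative fold-changes: with synergies strong enough for the planted
winners to be recovered reliably against per-sample response jitter, the
subgroup mean index under the winning condition is ~5–13× the NBE mean,
larger than the ~1.4–1.8× reported for real cohorts (whose NBE baseline
growth is far stronger relative to the planted gains). Passing recovery
tests therefore demonstrates that the pipeline's statistics identify
planted genotype–condition structure at realistic noise, not that real
screens show effects of this size.

**Expression model.** Paired GSC/tissue matrices share a per-sample latent
signal (sd 1.2, noise sd 0.5) for intrinsic genes (60% by default), while
microenvironment genes are independent between matrices; 8% of genes are
zeroed in 55–85% of samples and 5% flagged unannotated (both overlays avoid
the marker block) to exercise the intrinsic filter; subtype marker modules
(40 genes each) are shifted +2 in matching samples of both matrices, and a
30-gene module is shifted +1.2 in E&F-dependent stem cells so the
DEG→template surrogate-classification workflow has signal. Values are
clipped at zero, matching the log2(RPKM+1) floor.

## Numerical and interface choices

* All tabular interchange is UTF-8 TSV (labels contain "TGF-β"); writers
  prefix a comment header with the tool version and a config hash, readers
  skip `#` lines and validate schemas with row-located errors.
* Subgroup filters use a tiny parsed boolean language
  (`idh1_mut & !codel_1p19q`, `true_subtype == mesenchymal`) — no
  host-language `eval`.
* Seeds are explicit arguments everywhere; there is no hidden global RNG
  state, and equal seeds give bit-identical outputs (tested).
* Ranking ties: success rate desc, mean index desc, label asc. NTP and
  subtype ties: class-name order with a flag. Ward merge ties follow the
  scipy implementation; the oracle comparison uses continuous data where
  ties have measure zero.
* Degenerate inputs: zero-variance comparisons return p = 1 (equal means)
  or 0 rather than NaN; a zero reference mean yields a missing fold;
  constant genes get p = 1; an all-masked sample is a clustering error.

## Problem sizes

Tests and the acceptance script run the full 72-sample × 134-condition
screen across 20 seeds (screen-side recovery) and 1200-gene × 72-sample
expression across 10 seeds (transcriptome recovery), with 100–500
permutations for the permutation tests — sizes at which every recovery
statistic is stable while the whole suite runs in well under a minute per
stage.
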