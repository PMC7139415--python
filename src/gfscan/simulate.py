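"""Synthetic cohorts with planted genotype-dependent growth-factor effects.

Three generators cover the whole pipeline's input surface:

* :func:`generate_cohort` -- sample annotations (diagnosis, IDH1 / 1p19q /
  ATRX / BRAF and other mutation flags, a latent transcriptional subtype and
  a latent E&F-dependency group) at the frequencies of the published
  72-sample screen cohort.
* :func:`simulate_readouts` -- 384-well ATP-luminescence readouts under a
  log-linear growth model with additive per-factor effects, genotype-specific
  pair synergies and multiplicative log-normal measurement noise.
* :func:`simulate_expression` -- paired stem-cell / tissue log2(RPKM+1)
  matrices with an intrinsic/microenvironment gene split, planted subtype
  marker modules and zero-inflated genes.

Biology is intrinsic to a sample: its baseline rate and per-factor response
jitter are derived from a stable hash of the sample id, so re-simulating the
same sample under a different run seed reproduces its growth profile up to
measurement noise (mirroring a re-screen of an independently thawed vial).
The run seed controls only measurement noise.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .design import BASAL_IDS, CONTROL_NO_GF, ConditionCatalog, enumerate_conditions

__all__ = [
    "STUDY_COHORT",
    "CohortFrequencies",
    "GrowthModelParams",
    "reference_proportions",
    "cohort_summary",
    "generate_cohort",
    "expected_rate_matrix",
    "simulate_readouts",
    "simulate_expression",
]

SUBTYPES = ("classical", "mesenchymal", "proneural")
MUTATION_FLAGS = (
    "idh1_mut",
    "codel_1p19q",
    "atrx_mut",
    "braf_mut",
    "tp53_mut",
    "egfr_mut",
    "pten_mut",
    "cic_mut",
    "fubp1_mut",
    "notch1_mut",
)

#: Composition of the published 72-sample screen cohort (counts).
STUDY_COHORT = {
    "n_total": 72,
    "n_lgg": 19,
    "n_gbm": 53,
    "lgg_idh1_mut": 19,
    "gbm_idh1_mut": 6,
    "lgg_codel_1p19q": 9,
    "lgg_ef_independent": 14,
    "idh1_wt_ef_dependent": 26,
    "idh1_wt_ef_independent": 20,
    "proneural_in_ef_dependent": 9,
    "mesenchymal_in_ef_independent": 9,
    "classical_in_ef_independent": 9,
    "idh1_wt_proneural": 11,
    "idh1_wt_classical": 19,
    "idh1_wt_mesenchymal": 16,
}


def reference_proportions() -> dict[str, float]:
    """Headline cohort proportions (percent) from the study composition table."""
    c = STUDY_COHORT
    return {
        "lgg_ef_independent_pct": 100 * c["lgg_ef_independent"] / c["n_lgg"],
        "proneural_in_ef_dependent_pct": 100
        * c["proneural_in_ef_dependent"]
        / c["idh1_wt_ef_dependent"],
        "gbm_idh1_mut_pct": 100 * c["gbm_idh1_mut"] / c["n_gbm"],
        "lgg_1p19q_codel_pct": 100 * c["lgg_codel_1p19q"] / c["n_lgg"],
    }


def cohort_summary(cohort: pd.DataFrame) -> dict[str, float]:
    """Proportions (percent) computed from a cohort annotation table."""
    lgg = cohort[cohort["diagnosis"] == "LGG"]
    gbm = cohort[cohort["diagnosis"] == "GBM"]
    out: dict[str, float] = {"n_total": float(len(cohort)), "n_lgg": float(len(lgg))}
    if len(lgg):
        out["lgg_ef_independent_pct"] = 100 * (lgg["true_ef_group"] == "independent").mean()
        out["lgg_1p19q_codel_pct"] = 100 * lgg["codel_1p19q"].mean()
    if len(gbm):
        out["gbm_idh1_mut_pct"] = 100 * gbm["idh1_mut"].mean()
    dep_wt = cohort[(cohort["true_ef_group"] == "dependent") & ~cohort["idh1_mut"]]
    if len(dep_wt):
        out["proneural_in_ef_dependent_pct"] = 100 * (dep_wt["true_subtype"] == "proneural").mean()
    return out


@dataclass
class CohortFrequencies:
    """Genotype/annotation frequencies used by :func:`generate_cohort`.

    Defaults reproduce the published cohort composition: 19/72 lower-grade
    gliomas (all IDH1-mutant, 9/19 1p19q co-deleted), 6/53 IDH1-mutant
    glioblastomas, 72% of IDH1-mutant samples E&F-independent, and
    subtype-dependent E&F independence among IDH1-wild-type glioblastomas.
    """

    lgg_fraction: float = 19 / 72
    lgg_codel: float = 9 / 19
    gbm_idh1_mut: float = 6 / 53
    p_independent_idh1_mut: float = 0.72
    p_independent_by_subtype: dict = field(
        default_factory=lambda: {"proneural": 2 / 11, "classical": 9 / 19, "mesenchymal": 9 / 16}
    )
    subtype_probs: dict = field(
        default_factory=lambda: {"proneural": 11 / 46, "classical": 19 / 46, "mesenchymal": 16 / 46}
    )
    atrx_given_idh1_mut_intact: float = 0.7
    atrx_given_idh1_wt: float = 0.1
    braf_given_idh1_wt: float = 4 / 47
    tp53_given_idh1_mut_intact: float = 0.8
    tp53_given_codel: float = 0.2
    tp53_given_idh1_wt: float = 0.3
    egfr_given_idh1_wt: float = 0.5
    pten_given_idh1_wt: float = 0.4
    cic_given_codel: float = 0.5
    fubp1_given_codel: float = 0.3
    notch1_given_codel: float = 0.2
    background_mut: float = 0.03

    def validate(self) -> None:
        def _chk(name, v):
            if not 0 <= v <= 1:
                raise ValueError(f"frequency {name}={v} outside [0, 1]")

        for name, v in vars(self).items():
            if isinstance(v, dict):
                for k, p in v.items():
                    _chk(f"{name}[{k}]", p)
            else:
                _chk(name, v)
        if abs(sum(self.subtype_probs.values()) - 1) > 1e-9:
            raise ValueError("subtype_probs must sum to 1")


def generate_cohort(
    n: int = 72,
    frequencies: CohortFrequencies | None = None,
    seed: int = 0,
) -> pd.DataFrame:
    """Draw a cohort annotation table (index: sample_id).

    Structural constraints are enforced: every LGG is IDH1-mutant, 1p19q
    co-deletion implies IDH1 mutation, and ATRX mutation is mutually
    exclusive with co-deletion.  Latent truth columns (``true_subtype`` for
    IDH1-wild-type glioblastomas, ``true_ef_group`` for everyone) drive the
    growth and expression simulators and are the recovery targets for the
    downstream pipeline.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    freq = frequencies or CohortFrequencies()
    freq.validate()
    rng = np.random.default_rng(seed)
    n_lgg = int(round(n * freq.lgg_fraction))
    rows = []
    for i in range(n):
        sid = f"GS-{i + 1:03d}"
        is_lgg = i < n_lgg
        row = dict.fromkeys(MUTATION_FLAGS, False)
        row.update(sample_id=sid, diagnosis="LGG" if is_lgg else "GBM")
        if is_lgg:
            row["idh1_mut"] = True
            row["codel_1p19q"] = rng.random() < freq.lgg_codel
        else:
            row["idh1_mut"] = rng.random() < freq.gbm_idh1_mut
            row["codel_1p19q"] = False
        codel = row["codel_1p19q"]
        if row["idh1_mut"]:
            row["atrx_mut"] = (not codel) and rng.random() < freq.atrx_given_idh1_mut_intact
            row["tp53_mut"] = rng.random() < (
                freq.tp53_given_codel if codel else freq.tp53_given_idh1_mut_intact
            )
            row["cic_mut"] = rng.random() < (freq.cic_given_codel if codel else freq.background_mut)
            row["fubp1_mut"] = rng.random() < (
                freq.fubp1_given_codel if codel else freq.background_mut
            )
            row["notch1_mut"] = rng.random() < (
                freq.notch1_given_codel if codel else freq.background_mut
            )
            row["egfr_mut"] = rng.random() < freq.background_mut
            row["pten_mut"] = rng.random() < freq.background_mut
            row["true_subtype"] = ""
            p_indep = freq.p_independent_idh1_mut
        else:
            row["atrx_mut"] = rng.random() < freq.atrx_given_idh1_wt
            row["braf_mut"] = rng.random() < freq.braf_given_idh1_wt
            row["tp53_mut"] = rng.random() < freq.tp53_given_idh1_wt
            row["egfr_mut"] = rng.random() < freq.egfr_given_idh1_wt
            row["pten_mut"] = rng.random() < freq.pten_given_idh1_wt
            row["cic_mut"] = rng.random() < freq.background_mut
            row["fubp1_mut"] = rng.random() < freq.background_mut
            row["notch1_mut"] = rng.random() < freq.background_mut
            names = sorted(freq.subtype_probs)
            probs = np.array([freq.subtype_probs[s] for s in names])
            row["true_subtype"] = names[rng.choice(len(names), p=probs / probs.sum())]
            p_indep = freq.p_independent_by_subtype[row["true_subtype"]]
        row["true_ef_group"] = "independent" if rng.random() < p_indep else "dependent"
        rows.append(row)
    cohort = pd.DataFrame(rows).set_index("sample_id")
    return cohort


@dataclass
class GrowthModelParams:
    """Parameters of the log-linear six-day growth model.

    Per-day log-growth under a condition is the sample's baseline basal-media
    rate plus additive per-factor effects plus a genotype-specific synergy
    for designated factor pairs; readouts receive multiplicative log-normal
    noise.  Baseline rates are negative (cells decline slowly in factor-free
    basal media); the strongest planted combinations lift the total rate to
    doubling times of roughly 2-9 days.
    """

    baseline_log_rate_range: tuple[float, float] = (-0.08, -0.02)
    gf_effect: float = 0.01
    gf_effect_jitter_sd: float = 0.01
    ef_effect_dependent: float = 0.09  # per basal factor, per day
    ef_effect_independent: float = 0.01  # independence is relative, not absolute
    synergy: float = 0.15
    tgfb_atrx_boost: float = 0.08
    noise_sd: float = 0.05
    lum_per_cell: float = 10.0
    n_seeded: int = 1000
    horizon_days: float = 6.0

    def __post_init__(self) -> None:
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if self.horizon_days <= 0 or self.lum_per_cell <= 0:
            raise ValueError("horizon_days and lum_per_cell must be > 0")


#: Genotype-specific synergistic factor pairs: (pair, predicate name).
#: Mesenchymal IDH1-wild-type cells respond to PEDF+MDK, 1p19q-intact
#: IDH1-mutant cells to PlGF+IL-6, co-deleted IDH1-mutant cells to PEDF+SHH.
SYNERGY_RULES: tuple[tuple[frozenset, str], ...] = (
    (frozenset({"MDK", "PEDF"}), "mesenchymal_idh1_wt"),
    (frozenset({"IL-6", "PlGF"}), "idh1_mut_1p19q_intact"),
    (frozenset({"PEDF", "SHH"}), "idh1_mut_1p19q_codel"),
)


def _predicate(name: str, ann: pd.DataFrame) -> np.ndarray:
    if name == "mesenchymal_idh1_wt":
        return (~ann["idh1_mut"] & (ann["true_subtype"] == "mesenchymal")).to_numpy()
    if name == "idh1_mut_1p19q_intact":
        return (ann["idh1_mut"] & ~ann["codel_1p19q"]).to_numpy()
    if name == "idh1_mut_1p19q_codel":
        return (ann["idh1_mut"] & ann["codel_1p19q"]).to_numpy()
    raise KeyError(name)


def _intrinsic_rng(sample_id: str) -> np.random.Generator:
    # keyed to the sample id only: stable across run seeds
    return np.random.default_rng(zlib.crc32(f"gfscan:{sample_id}".encode()) & 0x7FFFFFFF)


def _sample_biology(cohort: pd.DataFrame, params: GrowthModelParams, factor_ids) -> tuple:
    lo, hi = params.baseline_log_rate_range
    baselines = np.empty(len(cohort))
    jitter = np.empty((len(cohort), len(factor_ids)))
    for i, sid in enumerate(cohort.index):
        rng = _intrinsic_rng(str(sid))
        baselines[i] = rng.uniform(lo, hi)
        jitter[i] = rng.normal(0.0, params.gf_effect_jitter_sd, size=len(factor_ids))
    return baselines, jitter


def expected_rate_matrix(
    cohort: pd.DataFrame,
    catalog: ConditionCatalog,
    params: GrowthModelParams | None = None,
) -> pd.DataFrame:
    """Noise-free per-day log-growth rates, samples x conditions.

    This is the model's closed form: ``exp(horizon * rate)`` is the expected
    D6/D0 ratio and ``exp(horizon * baseline)`` the expected N6/D0 ratio.
    """
    params = params or GrowthModelParams()
    factor_ids = sorted({f for c in catalog.conditions for f in c.factors} | set(BASAL_IDS))
    for c in catalog.conditions:
        unknown = c.factors - set(factor_ids)
        if unknown:
            raise ValueError(f"unknown growth factors in catalog: {sorted(unknown)}")
    fidx = {f: j for j, f in enumerate(factor_ids)}
    baselines, jitter = _sample_biology(cohort, params, factor_ids)
    dependent = (cohort["true_ef_group"] == "dependent").to_numpy()
    ef_per_factor = np.where(dependent, params.ef_effect_dependent, params.ef_effect_independent)
    tgfb_boost = (cohort["atrx_mut"] & cohort["idh1_mut"]).to_numpy() * params.tgfb_atrx_boost
    preds = {name: _predicate(name, cohort) for _, name in SYNERGY_RULES}

    rates = np.empty((len(cohort), len(catalog)))
    for j, cond in enumerate(catalog.conditions):
        r = baselines.copy()
        for f in cond.factors:
            r += params.gf_effect + jitter[:, fidx[f]]
            if f == "TGF-β":
                r += tgfb_boost
        for pair, pred_name in SYNERGY_RULES:
            if cond.factors == pair:
                r += preds[pred_name] * params.synergy
        if cond.with_ef:
            for f in BASAL_IDS:
                r += ef_per_factor + jitter[:, fidx[f]]
        rates[:, j] = r
    return pd.DataFrame(rates, index=cohort.index, columns=catalog.labels)


def simulate_readouts(
    cohort: pd.DataFrame,
    catalog: ConditionCatalog | None = None,
    params: GrowthModelParams | None = None,
    seed: int = 0,
    n_replicates: int = 2,
) -> pd.DataFrame:
    """Long-format luminescence readout table for a cohort.

    Emits D0 and D6 rows for every sample x condition x replicate plus one
    N6 series per sample (basal-media wells, carried under the NO_GF
    condition id).  Measurement noise is i.i.d. log-normal per well.
    """
    if len(cohort) == 0:
        raise ValueError("cohort is empty")
    catalog = catalog or enumerate_conditions()
    params = params or GrowthModelParams()
    rng = np.random.default_rng(seed)
    rates = expected_rate_matrix(cohort, catalog, params).to_numpy()
    n_s, n_c = rates.shape
    base = params.n_seeded * params.lum_per_cell
    h = params.horizon_days

    def noise(shape):
        if params.noise_sd == 0:
            return np.ones(shape)
        return np.exp(rng.normal(0.0, params.noise_sd, size=shape))

    d0 = base * noise((n_s, n_c, n_replicates))
    d6 = base * np.exp(h * rates)[:, :, None] * noise((n_s, n_c, n_replicates))
    baselines = np.array(
        [_intrinsic_rng(str(s)).uniform(*params.baseline_log_rate_range) for s in cohort.index]
    )
    n6 = base * np.exp(h * baselines)[:, None] * noise((n_s, n_replicates))

    sids = np.asarray(cohort.index)
    reps = np.arange(1, n_replicates + 1)
    frames = []
    for role, arr in (("D0", d0), ("D6", d6)):
        frames.append(
            pd.DataFrame(
                {
                    "sample_id": np.repeat(sids, n_c * n_replicates),
                    "condition_id": np.tile(np.repeat(catalog.labels, n_replicates), n_s),
                    "replicate": np.tile(reps, n_s * n_c),
                    "role": role,
                    "lum": arr.ravel(),
                }
            )
        )
    frames.append(
        pd.DataFrame(
            {
                "sample_id": np.repeat(sids, n_replicates),
                "condition_id": CONTROL_NO_GF,
                "replicate": np.tile(reps, n_s),
                "role": "N6",
                "lum": n6.ravel(),
            }
        )
    )
    return pd.concat(frames, ignore_index=True)


# ---------------------------------------------------------------------------
# expression simulator


@dataclass
class ExpressionModelParams:
    """Parameters of the paired stem-cell / tissue expression simulator."""

    baseline_range: tuple[float, float] = (2.0, 8.0)
    latent_sd: float = 1.2
    noise_sd: float = 0.5
    subtype_shift: float = 2.0
    ef_shift: float = 1.2
    n_subtype_markers: int = 40
    n_ef_markers: int = 30
    zero_inflated_fraction: float = 0.08
    unannotated_fraction: float = 0.05


def simulate_expression(
    cohort: pd.DataFrame,
    n_genes: int = 1200,
    intrinsic_fraction: float = 0.6,
    seed: int = 0,
    params: ExpressionModelParams | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Paired log2(RPKM+1) matrices for stem cells and parental tissues.

    Intrinsic genes share a per-sample latent signal between the two
    matrices (high cross-pair Spearman correlation); microenvironment genes
    are drawn independently.  Subtype marker modules are shifted up, in both
    matrices, in samples of the matching latent subtype, and an
    E&F-dependency module is shifted up in stem cells of dependent samples.
    A designated fraction of genes is zeroed in more than half the samples,
    and a fraction is flagged unannotated, to exercise the tumor-intrinsic
    filter.  Tissue columns are named ``<sample_id>-T``.

    Returns ``(gsc, tissue, truth)`` where ``truth`` records each gene's
    class, overlays and marker membership.
    """
    if not 0 < intrinsic_fraction < 1:
        raise ValueError("intrinsic_fraction must be in (0, 1)")
    if n_genes < 10:
        raise ValueError("n_genes must be >= 10")
    p = params or ExpressionModelParams()
    rng = np.random.default_rng(seed)
    n_s = len(cohort)
    genes = np.array([f"G{i + 1:05d}" for i in range(n_genes)])
    n_intrinsic = int(round(intrinsic_fraction * n_genes))
    klass = np.array(
        ["intrinsic"] * n_intrinsic + ["microenvironment"] * (n_genes - n_intrinsic)
    )

    mu = rng.uniform(*p.baseline_range, size=n_genes)
    shared = rng.normal(0.0, p.latent_sd, size=(n_genes, n_s))
    indep = rng.normal(0.0, p.latent_sd, size=(n_genes, n_s))
    gsc = mu[:, None] + np.where(
        (klass == "intrinsic")[:, None], shared, rng.normal(0.0, p.latent_sd, (n_genes, n_s))
    )
    tissue = mu[:, None] + np.where((klass == "intrinsic")[:, None], shared, indep)
    gsc += rng.normal(0.0, p.noise_sd, size=(n_genes, n_s))
    tissue += rng.normal(0.0, p.noise_sd, size=(n_genes, n_s))

    # marker modules live among intrinsic genes, in a fixed leading block;
    # module sizes shrink proportionally when the matrix is small
    n_marker = 3 * p.n_subtype_markers + p.n_ef_markers
    scale = min(1.0, max(0, n_intrinsic - 10) / n_marker)
    n_sub = max(2, int(p.n_subtype_markers * scale))
    n_ef = max(2, int(p.n_ef_markers * scale))
    marker_of = np.array([""] * n_genes, dtype=object)
    pos = 0
    for st in SUBTYPES:
        sel = slice(pos, pos + n_sub)
        marker_of[sel] = st
        members = (cohort["true_subtype"] == st).to_numpy()
        gsc[sel][:, members] += p.subtype_shift
        tissue[sel][:, members] += p.subtype_shift
        pos += n_sub
    ef_sel = slice(pos, pos + n_ef)
    marker_of[ef_sel] = "ef_dependent"
    dep = (cohort["true_ef_group"] == "dependent").to_numpy()
    gsc[ef_sel][:, dep] += p.ef_shift
    tissue[ef_sel][:, dep] += 0.5 * p.ef_shift

    # zero-inflation and annotation overlays avoid the marker block
    free = np.where(marker_of == "")[0]
    n_zero = int(round(p.zero_inflated_fraction * n_genes))
    n_unann = int(round(p.unannotated_fraction * n_genes))
    overlay = rng.choice(free, size=n_zero + n_unann, replace=False)
    zero_idx, unann_idx = overlay[:n_zero], overlay[n_zero:]
    zero_flag = np.zeros(n_genes, dtype=bool)
    zero_flag[zero_idx] = True
    annotated = np.ones(n_genes, dtype=bool)
    annotated[unann_idx] = False
    for g in zero_idx:
        frac = rng.uniform(0.55, 0.85)
        for mat in (gsc, tissue):
            cols = rng.choice(n_s, size=int(np.ceil(frac * n_s)), replace=False)
            mat[g, cols] = 0.0

    np.clip(gsc, 0.0, None, out=gsc)
    np.clip(tissue, 0.0, None, out=tissue)

    gsc_df = pd.DataFrame(gsc, index=genes, columns=cohort.index)
    tissue_df = pd.DataFrame(tissue, index=genes, columns=[f"{s}-T" for s in cohort.index])
    truth = pd.DataFrame(
        {
            "gene": genes,
            "klass": klass,
            "zero_inflated": zero_flag,
            "annotated": annotated,
            "marker_of": marker_of,
        }
    ).set_index("gene")
    return gsc_df, tissue_df, truth


def pair_map(cohort: pd.DataFrame) -> dict[str, str]:
    """Stem-cell -> parental-tissue column pairing for simulated expression."""
    return {str(s): f"{s}-T" for s in cohort.index}


def subtype_templates(truth: pd.DataFrame) -> dict[str, list[str]]:
    """Marker gene lists per latent subtype, from an expression truth table."""
    return {
        st: truth.index[truth["marker_of"] == st].tolist()
        for st in SUBTYPES
    }
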