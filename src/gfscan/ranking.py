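"""Condition ranking within genotype subgroups and mutation-condition
association screening.

The growth success rate of a condition is the fraction of evaluable samples
whose six-day growth rate D6/D0 strictly exceeds 1.  Conditions are ranked
by success rate (then mean index, then label) against the conventional NBE
reference, and every (mutated gene, condition) pair is screened with a
two-sided Wilcoxon rank-sum test on cell growth indices, with
Benjamini-Hochberg q-values reported alongside the raw p-values.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .design import CONTROL_NBE
from .screen import GrowthIndexMatrix

__all__ = [
    "growth_success_rate",
    "rank_conditions",
    "mutation_condition_screen",
    "bh_adjust",
    "wilcoxon_rank_sum",
]


def growth_success_rate(rates) -> tuple[float, int]:
    """(fraction of evaluable samples with rate > 1, n evaluable).

    NaN entries are masked samples and excluded from both numerator and
    denominator.
    """
    r = np.asarray(rates, dtype=float)
    r = r[np.isfinite(r)]
    if r.size == 0:
        raise ValueError("no evaluable samples")
    return float(np.mean(r > 1)), int(r.size)


def bh_adjust(pvalues) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values (monotone-enforced)."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p
    if np.any((p <= 0) | (p > 1)):
        raise ValueError("p-values must lie in (0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def wilcoxon_rank_sum(x, y) -> float:
    """Two-sided Wilcoxon rank-sum p-value.

    Uses the exact null distribution when both groups have <= 10
    observations and the pooled values carry no ties, and the normal
    approximation with tie correction otherwise.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    pooled = np.concatenate([x, y])
    exact = len(x) <= 10 and len(y) <= 10 and len(np.unique(pooled)) == pooled.size
    res = stats.mannwhitneyu(
        x, y, alternative="two-sided", method="exact" if exact else "asymptotic"
    )
    return float(res.pvalue)


def rank_conditions(
    m: GrowthIndexMatrix,
    subgroup,
    reference: str = CONTROL_NBE,
) -> pd.DataFrame:
    """Rank conditions for a sample subgroup.

    ``subgroup`` is a boolean mask or list of sample ids.  Per condition the
    table reports the growth success rate, the number of evaluable samples,
    the subgroup mean index, the fold-change vs the reference condition
    (ratio of subgroup mean indices over samples evaluable in both), a flag
    for exceeding the reference's success rate, and the rank (success rate
    desc, then mean index desc, then label).
    """
    if isinstance(subgroup, (pd.Series, np.ndarray)) and np.asarray(subgroup).dtype == bool:
        samples = m.index.index[np.asarray(subgroup)]
    else:
        samples = pd.Index(subgroup)
    if len(samples) == 0:
        raise ValueError("subgroup is empty")
    if reference not in m.index.columns:
        raise ValueError(f"reference condition {reference!r} not in matrix")
    idx = m.index.loc[samples]
    rates = m.rate.loc[samples]
    ref_idx = idx[reference]

    rows = []
    for cond in idx.columns:
        r = rates[cond].to_numpy(dtype=float)
        r = r[np.isfinite(r)]
        if r.size == 0:
            continue
        success, n = float(np.mean(r > 1)), int(r.size)
        both = idx[cond].notna() & ref_idx.notna()
        fold = np.nan
        if both.any():
            ref_mean = ref_idx[both].mean()
            if ref_mean != 0:
                fold = idx.loc[both, cond].mean() / ref_mean
        rows.append(
            {
                "condition_id": cond,
                "success_rate": success,
                "n_evaluable": n,
                "mean_index": float(idx[cond].mean()),
                "fold_vs_reference": float(fold) if np.isfinite(fold) else np.nan,
            }
        )
    out = pd.DataFrame(rows).set_index("condition_id")
    ref_success = out.loc[reference, "success_rate"] if reference in out.index else np.nan
    out["exceeds_reference"] = out["success_rate"] > ref_success
    out = out.sort_values(
        by=["success_rate", "mean_index", "condition_id"], ascending=[False, False, True]
    )
    out["rank"] = np.arange(1, len(out) + 1)
    return out


def mutation_condition_screen(
    m: GrowthIndexMatrix,
    annotations: pd.DataFrame,
    genes: list[str],
    restrict=None,
) -> pd.DataFrame:
    """Screen every (gene, condition) pair for a mutation-growth association.

    Per pair: delta = mean index(mutant) - mean index(wild-type) and a
    two-sided Wilcoxon rank-sum p on the indices; pairs where either group
    has fewer than 2 evaluable samples are skipped.  BH q-values are
    computed across all emitted pairs; ``mut_freq`` is the mutant fraction
    within the restricted sample set.
    """
    for g in genes:
        if g not in annotations.columns:
            raise KeyError(f"gene flag {g!r} absent from annotations")
    samples = m.index.index.intersection(annotations.index)
    if restrict is not None:
        if isinstance(restrict, (pd.Series, np.ndarray)) and np.asarray(restrict).dtype == bool:
            restrict = annotations.index[np.asarray(restrict)]
        samples = samples.intersection(pd.Index(restrict))
    idx = m.index.loc[samples]
    ann = annotations.loc[samples]

    rows = []
    for gene in genes:
        mut_mask = ann[gene].astype(bool)
        mut_freq = float(mut_mask.mean()) if len(mut_mask) else np.nan
        for cond in idx.columns:
            col = idx[cond]
            mut = col[mut_mask & col.notna()].to_numpy()
            wt = col[~mut_mask & col.notna()].to_numpy()
            if len(mut) < 2 or len(wt) < 2:
                continue
            rows.append(
                {
                    "gene": gene,
                    "condition_id": cond,
                    "delta": float(mut.mean() - wt.mean()),
                    "p": wilcoxon_rank_sum(mut, wt),
                    "n_mut": len(mut),
                    "n_wt": len(wt),
                    "mut_freq": mut_freq,
                }
            )
    out = pd.DataFrame(rows)
    if not out.empty:
        out["q"] = bh_adjust(out["p"].to_numpy())
    return out
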