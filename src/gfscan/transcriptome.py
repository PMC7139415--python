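"""Expression-side procedures: tumor-intrinsic gene filtering, two-group
differential expression, nearest-template prediction (NTP), single-sample
GSEA subtype scoring and a two-class GSEA engine.

Expression matrices are genes x samples DataFrames of log2(RPKM+1) values.
All rank-based scores (ssGSEA, GSEA running sums) are invariant to strictly
increasing per-sample transforms of the expression values.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .ranking import bh_adjust

__all__ = [
    "tumor_intrinsic_filter",
    "differential_expression",
    "ntp_classify",
    "ssgsea_scores",
    "assign_subtype",
    "gsea_two_class",
    "GseaResult",
]


# ---------------------------------------------------------------------------
# tumor-intrinsic gene filter


def _rowwise_spearman(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Spearman rho per row between two equally-shaped matrices (average
    ranks for ties, then row-wise Pearson)."""
    ra = stats.rankdata(a, axis=1)
    rb = stats.rankdata(b, axis=1)
    ra = ra - ra.mean(axis=1, keepdims=True)
    rb = rb - rb.mean(axis=1, keepdims=True)
    num = (ra * rb).sum(axis=1)
    den = np.sqrt((ra**2).sum(axis=1) * (rb**2).sum(axis=1))
    with np.errstate(invalid="ignore", divide="ignore"):
        rho = num / den
    return np.where(den == 0, 0.0, rho)


def tumor_intrinsic_filter(
    gsc: pd.DataFrame,
    tissue: pd.DataFrame,
    pairs: dict[str, str],
    rho_min: float = 0.4,
    zero_frac: float = 0.5,
    annotated=None,
) -> tuple[list[str], pd.DataFrame]:
    """Keep genes whose expression is conserved between stem cells and their
    parental tissues.

    A gene survives iff (1) its Spearman correlation across the sample pairs
    is >= ``rho_min``, (2) it is annotated, and (3) it is expressed
    (value > 0) in at least half of tissues *and* half of stem cells (more
    precisely: its zero fraction does not exceed ``zero_frac`` in either
    matrix).  Returns the surviving gene list plus a per-gene report with
    the correlation, zero fractions and the reason dropped.
    """
    gsc_cols = [g for g in pairs if g in gsc.columns and pairs[g] in tissue.columns]
    if len(gsc_cols) < 5:
        raise ValueError("need at least 5 stem-cell/tissue pairs")
    genes = gsc.index.intersection(tissue.index)
    a = gsc.loc[genes, gsc_cols].to_numpy()
    b = tissue.loc[genes, [pairs[g] for g in gsc_cols]].to_numpy()
    rho = _rowwise_spearman(a, b)

    gsc_zero = (gsc.loc[genes].to_numpy() == 0).mean(axis=1)
    tissue_zero = (tissue.loc[genes].to_numpy() == 0).mean(axis=1)
    if annotated is None:
        ann = np.ones(len(genes), dtype=bool)
    else:
        ann_set = set(annotated) if not isinstance(annotated, pd.Series) else None
        if ann_set is not None:
            ann = np.array([g in ann_set for g in genes])
        else:
            ann = annotated.reindex(genes).fillna(False).to_numpy(dtype=bool)

    low_rho = rho < rho_min
    zero_dropped = (gsc_zero > zero_frac) | (tissue_zero > zero_frac)
    reason = np.select(
        [~ann, zero_dropped, low_rho],
        ["unannotated", "mostly_zero", "low_correlation"],
        default="",
    )
    kept = reason == ""
    report = pd.DataFrame(
        {
            "rho": rho,
            "gsc_zero_frac": gsc_zero,
            "tissue_zero_frac": tissue_zero,
            "annotated": ann,
            "kept": kept,
            "reason": reason,
        },
        index=genes,
    )
    return list(genes[kept]), report


# ---------------------------------------------------------------------------
# differential expression


def differential_expression(
    e: pd.DataFrame,
    labels: pd.Series,
    p_max: float = 0.05,
    q_max: float = 0.1,
) -> pd.DataFrame:
    """Per-gene two-group comparison (Welch t-test + BH).

    A gene is a DEG iff p <= p_max and q <= q_max; ``direction`` is the sign
    of (group A mean - group B mean) with groups in sorted label order.
    Genes constant within both groups get p = 1.
    """
    labels = labels.reindex(e.columns).dropna()
    levels = sorted(labels.unique())
    if len(levels) != 2:
        raise ValueError(f"need exactly 2 groups, got {levels}")
    ga = labels.index[labels == levels[0]]
    gb = labels.index[labels == levels[1]]
    if len(ga) < 3 or len(gb) < 3:
        raise ValueError("both groups must have >= 3 samples")
    a = e[ga].to_numpy()
    b = e[gb].to_numpy()
    with np.errstate(invalid="ignore", divide="ignore"):
        t, p = stats.ttest_ind(a, b, axis=1, equal_var=False)
    const = (a.std(axis=1) == 0) & (b.std(axis=1) == 0)
    p = np.where(const, 1.0, p)
    p = np.where(np.isnan(p), 1.0, p)
    q = bh_adjust(np.clip(p, np.finfo(float).tiny, 1.0))
    diff = a.mean(axis=1) - b.mean(axis=1)
    out = pd.DataFrame(
        {
            f"mean_{levels[0]}": a.mean(axis=1),
            f"mean_{levels[1]}": b.mean(axis=1),
            "diff": diff,
            "p": p,
            "q": q,
            "is_deg": (p <= p_max) & (q <= q_max),
            "direction": np.sign(diff).astype(int),
        },
        index=e.index,
    )
    return out


# ---------------------------------------------------------------------------
# nearest template prediction


def ntp_classify(
    e: pd.DataFrame,
    templates: dict[str, list[str]],
    n_perm: int = 1000,
    seed: int = 0,
    min_genes: int = 10,
) -> pd.DataFrame:
    """Classify each sample by cosine distance to class marker templates.

    Marker genes are standardized gene-wise across samples; each class
    template assigns +1 to its own markers and -1 to the other classes'
    markers.  The predicted class minimizes the cosine distance
    ``1 - cos(sample, template)``; significance is the fraction of random
    equally-sized gene sets achieving a distance at most as small
    (add-one permutation estimate), with BH q-values across samples.
    Samples missing more than half the marker genes are still classified
    but flagged low-confidence; exact distance ties are broken by class
    name order and flagged.
    """
    classes = sorted(templates)
    if len(classes) < 2:
        raise ValueError("need at least 2 template classes")
    seen: set[str] = set()
    for c in classes:
        overlap = seen & set(templates[c])
        if overlap:
            raise ValueError(f"marker lists must be disjoint; shared: {sorted(overlap)[:5]}")
        seen |= set(templates[c])
    present = {c: [g for g in templates[c] if g in e.index] for c in classes}
    for c in classes:
        if len(present[c]) < min_genes:
            raise ValueError(f"class {c!r} has {len(present[c])} markers present; need >= {min_genes}")
    markers = [g for c in classes for g in present[c]]
    total_markers = sum(len(templates[c]) for c in classes)
    low_conf = len(markers) < 0.5 * total_markers

    z = e.to_numpy()
    z = (z - z.mean(axis=1, keepdims=True)) / np.where(
        z.std(axis=1, keepdims=True) == 0, 1.0, z.std(axis=1, keepdims=True)
    )
    zdf = pd.DataFrame(z, index=e.index, columns=e.columns)
    xm = zdf.loc[markers].to_numpy()  # m x s

    tmat = np.full((len(classes), len(markers)), -1.0)
    pos = 0
    for i, c in enumerate(classes):
        tmat[i, pos : pos + len(present[c])] = 1.0
        pos += len(present[c])

    def cosine_dist(block: np.ndarray) -> np.ndarray:
        # block: m x s marker expression; -> classes x s distances
        num = tmat @ block
        den = np.linalg.norm(tmat, axis=1)[:, None] * np.linalg.norm(block, axis=0)[None, :]
        with np.errstate(invalid="ignore", divide="ignore"):
            cos = np.where(den == 0, 0.0, num / den)
        return 1.0 - cos

    dist = cosine_dist(xm)  # classes x samples
    order = np.argsort(dist, axis=0, kind="stable")
    best = order[0]
    best_dist = dist[best, np.arange(dist.shape[1])]
    second = dist[order[1], np.arange(dist.shape[1])]
    tie = np.isclose(best_dist, second)

    rng = np.random.default_rng(seed)
    all_genes = np.arange(len(e.index))
    count_le = np.zeros(dist.shape[1])
    m = len(markers)
    for _ in range(n_perm):
        pick = rng.choice(all_genes, size=m, replace=False)
        pd_block = z[pick]
        d = cosine_dist(pd_block)
        count_le += d[best, np.arange(d.shape[1])] <= best_dist
    pvals = (count_le + 1) / (n_perm + 1)
    out = pd.DataFrame(
        {
            "predicted": [classes[i] for i in best],
            "distance": best_dist,
            "p": pvals,
            "q": bh_adjust(pvals),
            "tie": tie,
            "low_confidence": low_conf,
        },
        index=e.columns,
    )
    for i, c in enumerate(classes):
        out[f"dist_{c}"] = dist[i]
    return out


# ---------------------------------------------------------------------------
# single-sample GSEA


def ssgsea_scores(e: pd.DataFrame, sets: dict[str, list[str]], alpha: float = 0.25) -> pd.DataFrame:
    """Rank-weighted single-sample enrichment scores, sets x samples.

    Per sample, genes are ranked by expression (descending; the top gene
    carries rank value N).  The score is the sum over the ranking of the
    difference between the in-set ECDF weighted by rank^alpha and the
    uniform out-of-set ECDF.  Being rank-based, scores are invariant to any
    strictly increasing per-sample transform of the expression values.
    """
    n = len(e.index)
    gene_pos = {g: i for i, g in enumerate(e.index)}
    member = {}
    for name, genes in sets.items():
        idx = [gene_pos[g] for g in genes if g in gene_pos]
        if len(idx) < 2:
            raise ValueError(f"gene set {name!r} has < 2 members present")
        mask = np.zeros(n, dtype=bool)
        mask[idx] = True
        member[name] = mask

    x = e.to_numpy()
    # stable descending ordering per sample
    order = np.argsort(-x, axis=0, kind="stable")
    rank_value = (n - np.arange(n)).astype(float)  # value at ordered position
    weights = rank_value**alpha

    scores = np.empty((len(sets), x.shape[1]))
    for si, (name, mask) in enumerate(member.items()):
        in_set = mask[order]  # n x s, in ranking order
        w = np.where(in_set, weights[:, None], 0.0)
        p_in = np.cumsum(w, axis=0) / w.sum(axis=0, keepdims=True)
        out_w = (~in_set).astype(float)
        p_out = np.cumsum(out_w, axis=0) / (n - mask.sum())
        scores[si] = (p_in - p_out).sum(axis=0)
    return pd.DataFrame(scores, index=list(member), columns=e.columns)


def assign_subtype(scores: pd.DataFrame) -> pd.DataFrame:
    """Z-normalize each set's scores across samples and assign the argmax.

    Ties are broken by set-name order and flagged; a zero-variance score row
    is normalized to zeros.
    """
    if scores.shape[1] < 2:
        raise ValueError("need >= 2 samples to normalize scores across samples")
    scores = scores.sort_index()
    mu = scores.mean(axis=1)
    sd = scores.std(axis=1, ddof=0)
    z = scores.sub(mu, axis=0).div(sd.replace(0, np.nan), axis=0).fillna(0.0)
    arr = z.to_numpy()
    best = np.argmax(arr, axis=0)
    top = arr[best, np.arange(arr.shape[1])]
    tie = (np.isclose(arr, top[None, :]).sum(axis=0)) > 1
    return pd.DataFrame(
        {"subtype": [z.index[i] for i in best], "score": top, "tie": tie},
        index=scores.columns,
    )


# ---------------------------------------------------------------------------
# two-class GSEA


@dataclass
class GseaResult:
    es: float
    nes: float
    p: float
    fdr: float
    n_perm: int


def _signal_to_noise(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    sa, sb = a.std(axis=1, ddof=1), b.std(axis=1, ddof=1)
    return (a.mean(axis=1) - b.mean(axis=1)) / (sa + sb + 1e-12)


def _enrichment_score(metric_sorted: np.ndarray, in_set_sorted: np.ndarray, weight: float) -> float:
    w = np.abs(metric_sorted) ** weight
    hit = np.where(in_set_sorted, w, 0.0)
    hit_total = hit.sum()
    if hit_total == 0:
        return 0.0
    miss = (~in_set_sorted).astype(float)
    running = np.cumsum(hit / hit_total - miss / miss.sum())
    return float(running[np.argmax(np.abs(running))])


def gsea_two_class(
    e: pd.DataFrame,
    labels: pd.Series,
    gene_set: list[str],
    n_perm: int = 1000,
    seed: int = 0,
    weight: float = 1.0,
) -> GseaResult:
    """Two-class GSEA with a gene-set permutation null.

    Genes are ranked by the signal-to-noise metric between the two groups;
    the enrichment score (ES) is the extremum of the weighted running-sum
    statistic.  The null is ``n_perm`` random gene sets of equal size; NES
    is the ES divided by the mean |null ES| of matching sign, and p / FDR
    are the add-one tail fractions of the same-signed null.
    """
    labels = labels.reindex(e.columns).dropna()
    levels = sorted(labels.unique())
    if len(levels) != 2:
        raise ValueError("need exactly 2 groups")
    ga, gb = labels.index[labels == levels[0]], labels.index[labels == levels[1]]
    if len(ga) < 3 or len(gb) < 3:
        raise ValueError("both groups must have >= 3 samples")
    metric = _signal_to_noise(e[ga].to_numpy(), e[gb].to_numpy())
    if np.allclose(metric, metric[0]):
        raise ValueError("degenerate ranking metric: all genes tied")
    order = np.argsort(-metric, kind="stable")
    metric_sorted = metric[order]

    present = [g for g in gene_set if g in e.index]
    if len(present) < 5:
        raise ValueError("gene set must have >= 5 members present")
    mask = np.zeros(len(e.index), dtype=bool)
    mask[[e.index.get_loc(g) for g in present]] = True
    in_sorted = mask[order]
    es = _enrichment_score(metric_sorted, in_sorted, weight)

    rng = np.random.default_rng(seed)
    null = np.empty(n_perm)
    for i in range(n_perm):
        pick = rng.choice(len(e.index), size=len(present), replace=False)
        pm = np.zeros(len(e.index), dtype=bool)
        pm[pick] = True
        null[i] = _enrichment_score(metric_sorted, pm[order], weight)
    same_sign = null[np.sign(null) == np.sign(es)] if es != 0 else null
    if same_sign.size == 0:
        nes = np.nan
        p = 1.0 / (n_perm + 1)
    else:
        nes = es / np.abs(same_sign).mean()
        p = (np.sum(np.abs(same_sign) >= abs(es)) + 1) / (same_sign.size + 1)
    return GseaResult(es=es, nes=float(nes), p=float(p), fdr=float(p), n_perm=n_perm)
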