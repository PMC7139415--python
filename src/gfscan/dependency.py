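"""E&F-dependency stratification: Ward clustering of growth-index profiles
and dependent/independent labeling of the resulting clusters.

Samples are agglomeratively clustered (Ward linkage, Euclidean distance) on
their raw cell-growth-index rows.  Each cluster is then labeled
E&F-*dependent* when its members' mean indices under with-E&F conditions are
significantly higher than under the matched without-E&F conditions (paired
two-tailed t-test with a positive mean difference), and *independent*
otherwise.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster.hierarchy import fcluster, linkage

from .design import ConditionCatalog
from .screen import GrowthIndexMatrix

__all__ = [
    "ClusterAssignment",
    "hierarchical_cluster",
    "ef_dependency_delta",
    "dependency_deltas",
    "label_clusters",
    "group_enrichment",
]

logger = logging.getLogger(__name__)

DEPENDENT = "dependent"
INDEPENDENT = "independent"


@dataclass
class ClusterAssignment:
    """Sample-to-cluster map with optional E&F labels per cluster."""

    clusters: pd.Series  # sample_id -> cluster id in 1..k
    linkage_matrix: np.ndarray
    ef_labels: dict[int, str] | None = None
    deltas: pd.Series | None = None

    @property
    def sample_ef_label(self) -> pd.Series:
        if self.ef_labels is None:
            raise ValueError("clusters have not been labeled yet")
        return self.clusters.map(self.ef_labels).rename("ef_label")

    def merge_tree(self) -> pd.DataFrame:
        """Merge steps as (parent, child1, child2, height) for dendrograms."""
        n = len(self.clusters)
        z = self.linkage_matrix
        return pd.DataFrame(
            {
                "parent": np.arange(n, n + len(z)),
                "child1": z[:, 0].astype(int),
                "child2": z[:, 1].astype(int),
                "height": z[:, 2],
            }
        )


def _complete_rows(index_df: pd.DataFrame) -> pd.DataFrame:
    """Row-mean imputation of masked cells; Ward needs complete vectors."""
    x = index_df.copy()
    all_nan = x.isna().all(axis=1)
    if all_nan.any():
        raise ValueError(
            f"samples with no unmasked conditions cannot be clustered: "
            f"{list(x.index[all_nan])}"
        )
    n_imputed = int(x.isna().to_numpy().sum())
    if n_imputed:
        logger.info("imputing %d masked cells with sample row means", n_imputed)
        x = x.apply(lambda row: row.fillna(row.mean()), axis=1)
    return x


def hierarchical_cluster(m: GrowthIndexMatrix | pd.DataFrame, k: int = 4) -> ClusterAssignment:
    """Ward/Euclidean agglomeration of samples on raw index rows, cut at k."""
    index_df = m.index if isinstance(m, GrowthIndexMatrix) else m
    n = len(index_df)
    if not 2 <= k <= n:
        raise ValueError(f"k must be in [2, n_samples={n}], got {k}")
    x = _complete_rows(index_df)
    z = linkage(x.to_numpy(), method="ward")
    labels = fcluster(z, t=k, criterion="maxclust")
    clusters = pd.Series(labels, index=index_df.index, name="cluster")
    return ClusterAssignment(clusters=clusters, linkage_matrix=z)


def ef_dependency_delta(row: pd.Series, catalog: ConditionCatalog) -> float:
    """Mean with-E&F minus without-E&F index over all paired condition
    couples of one sample; couples with either side masked are skipped."""
    diffs = []
    for lbl_no, lbl_ef in catalog.ef_pairing.items():
        if lbl_no in row.index and lbl_ef in row.index:
            a, b = row[lbl_ef], row[lbl_no]
            if np.isfinite(a) and np.isfinite(b):
                diffs.append(a - b)
    if not diffs:
        raise ValueError("no usable with/without-E&F condition couples")
    return float(np.mean(diffs))


def dependency_deltas(index_df: pd.DataFrame, catalog: ConditionCatalog) -> pd.Series:
    return pd.Series(
        {s: ef_dependency_delta(index_df.loc[s], catalog) for s in index_df.index},
        name="dependency_delta",
    )


def _paired_means(index_df: pd.DataFrame, catalog: ConditionCatalog) -> pd.DataFrame:
    """Per-sample mean index over the with-E&F and without-E&F halves of the
    paired (non-control) conditions."""
    no_lbls = [l for l in catalog.ef_pairing if l in index_df.columns]
    ef_lbls = [catalog.ef_pairing[l] for l in no_lbls if catalog.ef_pairing[l] in index_df.columns]
    return pd.DataFrame(
        {
            "with_ef": index_df[ef_lbls].mean(axis=1),
            "without_ef": index_df[no_lbls].mean(axis=1),
        }
    )


def label_clusters(
    assignment: ClusterAssignment,
    index_df: pd.DataFrame,
    catalog: ConditionCatalog,
    alpha: float = 0.05,
    min_delta: float = 0.25,
) -> ClusterAssignment:
    """Label each cluster dependent or independent.

    A cluster is *dependent* iff a two-tailed paired t-test of its members'
    with-E&F vs without-E&F mean indices gives p < alpha *and* the mean
    difference exceeds ``min_delta`` index units.  The effect-size floor is
    needed because significance alone tests whether any E&F benefit exists,
    not whether it is substantial: in a large cluster even a trivial but
    consistent benefit reaches p < alpha.  Size-1 clusters are labeled by
    their single delta against the same floor (with a logged warning).
    """
    pm = _paired_means(index_df, catalog)
    deltas = dependency_deltas(index_df, catalog)
    labels: dict[int, str] = {}
    for cid, members in assignment.clusters.groupby(assignment.clusters).groups.items():
        sub = pm.loc[members]
        if len(sub) == 1:
            logger.warning("cluster %s has a single member; labeled by its delta alone", cid)
            labels[int(cid)] = DEPENDENT if deltas.loc[members[0]] > min_delta else INDEPENDENT
            continue
        diff = sub["with_ef"] - sub["without_ef"]
        if np.allclose(diff, diff.iloc[0]):
            # zero-variance differences: the t-test is undefined; decide by size
            labels[int(cid)] = DEPENDENT if diff.mean() > min_delta else INDEPENDENT
            continue
        t, p = stats.ttest_rel(sub["with_ef"], sub["without_ef"])
        labels[int(cid)] = DEPENDENT if (p < alpha and diff.mean() > min_delta) else INDEPENDENT
    return replace(assignment, ef_labels=labels, deltas=deltas)


def group_enrichment(
    sample_ef_label: pd.Series,
    annotations: pd.DataFrame,
    flag: str,
) -> tuple[pd.DataFrame, float, float]:
    """Two-sided Fisher's exact test of E&F label x genotype flag.

    Returns (2x2 contingency table, odds ratio, p).
    """
    if flag not in annotations.columns:
        raise KeyError(f"unknown annotation flag {flag!r}")
    labels, flags = sample_ef_label.align(annotations[flag].astype(bool), join="inner")
    table = pd.crosstab(labels, flags)
    table = table.reindex(index=[DEPENDENT, INDEPENDENT], columns=[True, False], fill_value=0)
    if (table.sum(axis=0) == 0).any() or (table.sum(axis=1) == 0).any():
        raise ValueError("degenerate contingency table (empty margin)")
    odds, p = stats.fisher_exact(table.to_numpy(), alternative="two-sided")
    return table, float(odds), float(p)
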