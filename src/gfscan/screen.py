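"""Screen-level statistics: QC filtering, replicate aggregation and the
cell growth index.

The screen reads each well three ways: luminescence at seeding (``D0``),
after six days under the test condition (``D6``), and after six days in
basal media without growth factors (``N6``; one series per sample).  The
cell growth index is ``(D6 - N6) / D0`` -- growth attributable to the
supplied factors over basal survival -- and the growth rate is ``D6 / D0``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .design import CONTROL_NO_GF, ConditionCatalog

__all__ = [
    "READOUT_COLUMNS",
    "GrowthIndexMatrix",
    "cell_growth_index",
    "qc_filter",
    "build_index_matrix",
    "replicate_concordance",
    "group_growth_comparison",
]

logger = logging.getLogger(__name__)

READOUT_COLUMNS = ("sample_id", "condition_id", "replicate", "role", "lum")
ROLES = ("D0", "D6", "N6")

#: Wells with a day-6 ATP-luminescence signal at or below this level are
#: treated as containing too few viable cells to score.
DEFAULT_MIN_SIGNAL = 5000.0
#: Wells whose day-6 / day-0 luminescence ratio is at or below this level
#: are treated as failed cultures.
DEFAULT_MIN_RATIO = 0.5


def cell_growth_index(d0: float, d6: float, n6: float) -> float:
    """``(d6 - n6) / d0``; may be negative when a condition underperforms
    basal media."""
    if d0 <= 0:
        raise ValueError(f"D0 luminescence must be > 0, got {d0}")
    if d6 < 0 or n6 < 0:
        raise ValueError("luminescence values must be >= 0")
    return (d6 - n6) / d0


def validate_readouts(t: pd.DataFrame) -> pd.DataFrame:
    """Check the readout-table schema and invariants; returns the table."""
    missing = set(READOUT_COLUMNS) - set(t.columns)
    if missing:
        raise ValueError(f"readout table missing columns: {sorted(missing)}")
    bad_role = ~t["role"].isin(ROLES)
    if bad_role.any():
        rows = t.index[bad_role][:5].tolist()
        raise ValueError(f"unknown readout role at rows {rows}")
    if (t["lum"] < 0).any():
        rows = t.index[t["lum"] < 0][:5].tolist()
        raise ValueError(f"negative luminescence at rows {rows}")
    key = ["sample_id", "condition_id", "replicate", "role"]
    dup = t.duplicated(subset=key)
    if dup.any():
        rows = t.index[dup][:5].tolist()
        raise ValueError(f"duplicate (sample, condition, replicate, role) at rows {rows}")
    n6 = t[t["role"] == "N6"]
    if not n6.empty and (n6["condition_id"] != CONTROL_NO_GF).any():
        raise ValueError(f"N6 rows must carry the {CONTROL_NO_GF} condition id")
    return t


def _replicate_table(t: pd.DataFrame) -> pd.DataFrame:
    """Wide per-(sample, condition, replicate) table with d0/d6 columns for
    every replicate that has a D6 measurement."""
    sub = t[t["role"].isin(["D0", "D6"])]
    wide = sub.pivot_table(
        index=["sample_id", "condition_id", "replicate"],
        columns="role",
        values="lum",
        aggfunc="first",
    ).reset_index()
    wide.columns.name = None
    for col in ("D0", "D6"):
        if col not in wide.columns:
            wide[col] = np.nan
    return wide[wide["D6"].notna()].rename(columns={"D0": "d0", "D6": "d6"})


def qc_filter(
    t: pd.DataFrame,
    min_signal: float = DEFAULT_MIN_SIGNAL,
    min_ratio: float = DEFAULT_MIN_RATIO,
) -> pd.DataFrame:
    """Per-well QC: a (sample, condition, replicate) triple passes iff its D6
    luminescence strictly exceeds ``min_signal`` and its D6/D0 ratio strictly
    exceeds ``min_ratio``.

    Returns one row per measured triple with columns ``d0, d6, ratio,
    pass_signal, pass_ratio, qc_pass, reason``.  A D6 row lacking its D0
    partner fails with reason ``missing_D0`` (logged, not raised).
    """
    if min_signal < 0 or min_ratio < 0:
        raise ValueError("QC thresholds must be >= 0")
    validate_readouts(t)
    wide = _replicate_table(t).copy()
    with np.errstate(divide="ignore", invalid="ignore"):
        wide["ratio"] = wide["d6"] / wide["d0"]
    missing_d0 = wide["d0"].isna() | (wide["d0"] <= 0)
    if missing_d0.any():
        logger.warning(
            "%d wells have a D6 readout without a usable D0; marked as QC failures",
            int(missing_d0.sum()),
        )
    wide["pass_signal"] = wide["d6"] > min_signal
    wide["pass_ratio"] = wide["ratio"] > min_ratio
    wide.loc[missing_d0, "pass_ratio"] = False
    wide["qc_pass"] = wide["pass_signal"] & wide["pass_ratio"] & ~missing_d0
    reason = np.where(
        missing_d0,
        "missing_D0",
        np.where(
            ~wide["pass_signal"] & ~wide["pass_ratio"],
            "low_signal;low_ratio",
            np.where(~wide["pass_signal"], "low_signal", np.where(~wide["pass_ratio"], "low_ratio", "")),
        ),
    )
    wide["reason"] = reason
    return wide


@dataclass
class GrowthIndexMatrix:
    """Samples x conditions growth statistics with QC provenance.

    ``index`` holds the cell growth index, ``rate`` the D6/D0 growth rate,
    ``qc_pass`` whether at least one replicate survived QC (masked cells are
    NaN in both matrices) and ``n_replicates`` how many replicates each cell
    was computed from.
    """

    index: pd.DataFrame
    rate: pd.DataFrame
    qc_pass: pd.DataFrame
    n_replicates: pd.DataFrame

    @property
    def samples(self) -> list[str]:
        return list(self.index.index)

    @property
    def conditions(self) -> list[str]:
        return list(self.index.columns)


def build_index_matrix(
    t: pd.DataFrame,
    catalog: ConditionCatalog,
    min_signal: float = DEFAULT_MIN_SIGNAL,
    min_ratio: float = DEFAULT_MIN_RATIO,
) -> GrowthIndexMatrix:
    """Aggregate technical replicates and compute the growth statistics.

    Replicate luminescence values are averaged per role *before* applying the
    index formula (N6 is a per-sample background, so role-level averaging is
    the consistent choice); only QC-passing replicates contribute.  The
    per-sample N6 level is the mean of its N6-role readouts, which are taken
    at face value rather than QC-filtered -- they measure basal survival, the
    quantity the viability QC rule is designed to reject.
    """
    qc = qc_filter(t, min_signal=min_signal, min_ratio=min_ratio)
    n6 = t[t["role"] == "N6"].groupby("sample_id")["lum"].mean()

    passing = qc[qc["qc_pass"]]
    agg = passing.groupby(["sample_id", "condition_id"]).agg(
        d0=("d0", "mean"), d6=("d6", "mean"), n=("d6", "size")
    ).reset_index()

    samples = sorted(t["sample_id"].unique())
    cols = [lbl for lbl in catalog.labels if lbl in set(t["condition_id"])]

    no_n6 = [s for s in samples if s not in n6.index]
    if no_n6:
        logger.warning("samples without N6 measurements are fully masked: %s", no_n6)

    def _pivot(col):
        return agg.pivot(index="sample_id", columns="condition_id", values=col).reindex(
            index=samples, columns=cols
        )

    d0m, d6m = _pivot("d0"), _pivot("d6")
    n6_per_sample = n6.reindex(samples)
    shape_index = d6m.sub(n6_per_sample, axis=0).div(d0m)
    rate = d6m.div(d0m)
    rate[shape_index.isna()] = np.nan  # one mask for both statistics
    nrep = _pivot("n").fillna(0).astype(int)
    nrep[shape_index.isna()] = 0

    return GrowthIndexMatrix(
        index=shape_index, rate=rate, qc_pass=shape_index.notna(), n_replicates=nrep
    )


def replicate_concordance(run_a: pd.Series, run_b: pd.Series) -> float:
    """Squared Pearson correlation of two growth-index profiles of the same
    sample over their shared unmasked conditions."""
    a, b = run_a.align(run_b, join="inner")
    ok = a.notna() & b.notna()
    if ok.sum() < 3:
        raise ValueError("need at least 3 shared unmasked conditions")
    r = np.corrcoef(a[ok], b[ok])[0, 1]
    return float(r**2)


def group_growth_comparison(values, groups) -> tuple[dict, float]:
    """Two-tailed Welch t-test of a per-sample growth statistic between two
    groups; returns ({group: mean}, p)."""
    values = np.asarray(values, dtype=float)
    groups = np.asarray(groups)
    levels = pd.unique(groups)
    if len(levels) != 2:
        raise ValueError(f"need exactly 2 groups, got {len(levels)}")
    x = values[groups == levels[0]]
    y = values[groups == levels[1]]
    if len(x) < 2 or len(y) < 2:
        raise ValueError("both groups must have >= 2 observations")
    means = {levels[0]: float(np.mean(x)), levels[1]: float(np.mean(y))}
    if np.var(x) == 0 and np.var(y) == 0:
        # degenerate: no spread anywhere -> decided by the means alone
        return means, 1.0 if np.mean(x) == np.mean(y) else 0.0
    t, p = stats.ttest_ind(x, y, equal_var=False)
    return means, float(p)
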