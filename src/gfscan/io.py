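"""Readers and writers for the pipeline's TSV/GMT interchange formats.

All tabular files are UTF-8 TSV (growth-factor and condition labels contain
characters like "TGF-β" and commas are reserved for prose).  Writers prefix
a comment header with the tool version and, when available, a configuration
hash; readers skip ``#`` lines.
"""

from __future__ import annotations

import hashlib
from pathlib import Path

import pandas as pd

from . import __version__
from .design import Condition, ConditionCatalog, parse_label
from .screen import GrowthIndexMatrix, validate_readouts

__all__ = [
    "config_hash",
    "write_tsv",
    "read_readouts",
    "write_readouts",
    "read_annotations",
    "write_annotations",
    "read_expression",
    "write_expression",
    "read_gmt",
    "write_gmt",
    "read_catalog",
    "write_catalog",
    "read_index_matrix",
    "write_index_matrix",
]

BOOL_COLUMNS_HINT = ("_mut", "codel_1p19q")


def config_hash(obj) -> str:
    """Short stable hash of a configuration mapping."""
    return hashlib.sha256(repr(sorted(str(obj).split())).encode()).hexdigest()[:10]


def _header(extra: str = "") -> str:
    line = f"# gfscan v{__version__}"
    if extra:
        line += f" {extra}"
    return line + "\n"


def write_tsv(df: pd.DataFrame, path, index: bool = False, extra: str = "") -> None:
    path = Path(path)
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(_header(extra))
        df.to_csv(fh, sep="\t", index=index)


def _read_tsv(path, **kw) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#", encoding="utf-8", **kw)


# -- readouts ---------------------------------------------------------------


def read_readouts(path) -> pd.DataFrame:
    t = _read_tsv(path)
    required = {"sample_id", "condition_id", "replicate", "role", "lum"}
    missing = required - set(t.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    return validate_readouts(t)


def write_readouts(t: pd.DataFrame, path, extra: str = "") -> None:
    write_tsv(t, path, extra=extra)


# -- annotations ------------------------------------------------------------


def read_annotations(path) -> pd.DataFrame:
    t = _read_tsv(path)
    if "sample_id" not in t.columns:
        raise ValueError(f"{path}: missing sample_id column")
    if t["sample_id"].duplicated().any():
        raise ValueError(f"{path}: duplicate sample ids")
    t = t.set_index("sample_id")
    for col in t.columns:
        if col.endswith(BOOL_COLUMNS_HINT[0]) or col in BOOL_COLUMNS_HINT:
            t[col] = t[col].astype(bool)
    return t


def write_annotations(ann: pd.DataFrame, path, extra: str = "") -> None:
    write_tsv(ann.reset_index(), path, extra=extra)


# -- expression -------------------------------------------------------------


def read_expression(path) -> pd.DataFrame:
    e = _read_tsv(path, index_col=0)
    if e.index.duplicated().any():
        raise ValueError(f"{path}: duplicate gene ids")
    if (e.to_numpy() < 0).any():
        raise ValueError(f"{path}: negative expression values")
    return e


def write_expression(e: pd.DataFrame, path, extra: str = "") -> None:
    out = e.copy()
    out.index.name = out.index.name or "gene"
    write_tsv(out, path, index=True, extra=extra)


# -- gene sets (GMT) --------------------------------------------------------


def read_gmt(path) -> dict[str, list[str]]:
    sets: dict[str, list[str]] = {}
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ValueError(f"{path}:{lineno}: GMT line needs name, description, >=1 gene")
            name, genes = parts[0], [g for g in parts[2:] if g]
            if name in sets:
                raise ValueError(f"{path}:{lineno}: duplicate gene set {name!r}")
            if not genes:
                raise ValueError(f"{path}:{lineno}: empty gene set {name!r}")
            sets[name] = genes
    return sets


def write_gmt(sets: dict[str, list[str]], path, description: str = "") -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for name, genes in sets.items():
            fh.write("\t".join([name, description, *genes]) + "\n")


# -- condition catalog ------------------------------------------------------


def read_catalog(path) -> ConditionCatalog:
    t = _read_tsv(path)
    if "condition_id" not in t.columns:
        raise ValueError(f"{path}: missing condition_id column")
    conditions = [parse_label(lbl) for lbl in t["condition_id"]]
    return ConditionCatalog(conditions)


def write_catalog(catalog: ConditionCatalog, path, extra: str = "") -> None:
    rows = []
    for c in catalog.conditions:
        fac = sorted(c.factors, key=lambda s: (s.lower(), s))
        rows.append(
            {
                "condition_id": c.label,
                "factor_1": fac[0] if fac else "",
                "factor_2": fac[1] if len(fac) > 1 else "",
                "with_ef": c.with_ef,
                "kind": c.kind,
            }
        )
    write_tsv(pd.DataFrame(rows), path, extra=extra)


# -- growth index matrix ----------------------------------------------------


def write_index_matrix(m: GrowthIndexMatrix, prefix, extra: str = "") -> None:
    """Write index/rate/replicate-count matrices as ``<prefix>.<part>.tsv``."""
    prefix = Path(prefix)
    for part, df in (("index", m.index), ("rate", m.rate), ("n_replicates", m.n_replicates)):
        out = df.copy()
        out.index.name = "sample_id"
        write_tsv(out, f"{prefix}.{part}.tsv", index=True, extra=extra)


def read_index_matrix(prefix) -> GrowthIndexMatrix:
    prefix = Path(prefix)
    index = _read_tsv(f"{prefix}.index.tsv", index_col=0)
    rate = _read_tsv(f"{prefix}.rate.tsv", index_col=0)
    nrep = _read_tsv(f"{prefix}.n_replicates.tsv", index_col=0)
    return GrowthIndexMatrix(index=index, rate=rate, qc_pass=index.notna(), n_replicates=nrep)
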