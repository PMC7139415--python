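"""Condition catalog for growth-factor (GF) combination screens.

A screening panel consists of two basal factors -- EGF and bFGF, jointly
referred to as E&F -- plus a set of candidate growth factors.  The screen
evaluates every single candidate factor and every unordered pair of
candidate factors, each once with and once without E&F added, alongside two
controls: basal media with no growth factors at all (``NO_GF``) and basal
media supplemented with E&F alone (``NBE``, the conventional glioma-stem-cell
culture condition).  For ``m`` candidate factors this yields
``2 * (C(m, 2) + m)`` non-control conditions; the default 11-factor glioma
panel gives 132.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field
from functools import cached_property

import pandas as pd

__all__ = [
    "GrowthFactor",
    "Condition",
    "ConditionCatalog",
    "DEFAULT_PANEL",
    "BASAL_IDS",
    "CONTROL_NO_GF",
    "CONTROL_NBE",
    "canonical_label",
    "parse_label",
    "enumerate_conditions",
    "plate_layout",
]

BASAL_IDS = ("EGF", "bFGF")
CONTROL_NO_GF = "NO_GF"
CONTROL_NBE = "NBE"

KIND_SINGLE = "single"
KIND_PAIR = "pair"
KIND_CONTROL_NO_GF = "control_no_gf"
KIND_CONTROL_NBE = "control_nbe"

#: ASCII fallbacks accepted on input for factor ids containing non-ASCII or
#: punctuation-sensitive characters.
FACTOR_ALIASES = {
    "TGFB": "TGF-β",
    "TGF-B": "TGF-β",
    "IL6": "IL-6",
    "PLGF": "PlGF",
    "SEMA3A": "Sema3A",
    "NRG1": "NRG-1",
}


@dataclass(frozen=True)
class GrowthFactor:
    """One growth factor of a screening panel.

    Concentrations are carried as metadata only (ng/mL); no computation
    depends on them.
    """

    id: str
    name: str = ""
    concentration: float = 1.0
    is_basal: bool = False

    def __post_init__(self) -> None:
        if not self.id:
            raise ValueError("growth factor id must be non-empty")
        if self.concentration <= 0:
            raise ValueError(f"concentration must be > 0, got {self.concentration}")


#: The default screening panel: E&F at 5 ng/mL plus 11 glioma-associated
#: growth factors at 1 ng/mL.
DEFAULT_PANEL: tuple[GrowthFactor, ...] = (
    GrowthFactor("EGF", "epidermal growth factor", 5.0, is_basal=True),
    GrowthFactor("bFGF", "basic fibroblast growth factor", 5.0, is_basal=True),
    GrowthFactor("IGF1", "insulin-like growth factor 1"),
    GrowthFactor("NRG-1", "neuregulin 1"),
    GrowthFactor("HGF", "hepatocyte growth factor"),
    GrowthFactor("PDGF", "platelet-derived growth factor"),
    GrowthFactor("PlGF", "placental growth factor"),
    GrowthFactor("PEDF", "pigment epithelium-derived factor"),
    GrowthFactor("Sema3A", "semaphorin 3A"),
    GrowthFactor("TGF-β", "transforming growth factor beta"),
    GrowthFactor("IL-6", "interleukin 6"),
    GrowthFactor("SHH", "sonic hedgehog"),
    GrowthFactor("MDK", "midkine"),
)


def _sorted_factors(factors) -> list[str]:
    # case-insensitive alphabetical; exact string as tie-break
    return sorted(factors, key=lambda s: (s.lower(), s))


@dataclass(frozen=True)
class Condition:
    """One culture condition: a set of candidate factors plus an E&F flag."""

    factors: frozenset[str]
    with_ef: bool
    kind: str

    def __post_init__(self) -> None:
        if self.kind in (KIND_CONTROL_NO_GF, KIND_CONTROL_NBE):
            if self.factors:
                raise ValueError("control conditions carry no candidate factors")
            expect_ef = self.kind == KIND_CONTROL_NBE
            if self.with_ef is not expect_ef:
                raise ValueError(f"{self.kind} must have with_ef={expect_ef}")
        elif self.kind == KIND_SINGLE:
            if len(self.factors) != 1:
                raise ValueError("single condition must have exactly 1 factor")
        elif self.kind == KIND_PAIR:
            if len(self.factors) != 2:
                raise ValueError("pair condition must have exactly 2 distinct factors")
        else:
            raise ValueError(f"unknown condition kind {self.kind!r}")

    @property
    def label(self) -> str:
        return canonical_label(self)

    @property
    def is_control(self) -> bool:
        return self.kind in (KIND_CONTROL_NO_GF, KIND_CONTROL_NBE)


def canonical_label(c: Condition) -> str:
    """Deterministic label: factors in case-insensitive alphabetical order,
    ``/E&F`` suffix when E&F is present; controls are ``NO_GF`` and ``NBE``."""
    if c.kind == KIND_CONTROL_NO_GF:
        return CONTROL_NO_GF
    if c.kind == KIND_CONTROL_NBE:
        return CONTROL_NBE
    parts = _sorted_factors(c.factors)
    if c.with_ef:
        parts.append("E&F")
    return "/".join(parts)


def parse_label(label: str) -> Condition:
    """Inverse of :func:`canonical_label`; honors ASCII aliases (TGFB → TGF-β)."""
    label = label.strip()
    if label == CONTROL_NO_GF:
        return Condition(frozenset(), False, KIND_CONTROL_NO_GF)
    if label == CONTROL_NBE:
        return Condition(frozenset(), True, KIND_CONTROL_NBE)
    tokens = [t.strip() for t in label.split("/") if t.strip()]
    if not tokens:
        raise ValueError(f"cannot parse condition label {label!r}")
    with_ef = False
    if tokens[-1].upper() == "E&F":
        with_ef = True
        tokens = tokens[:-1]
    factors = frozenset(FACTOR_ALIASES.get(t.upper(), t) for t in tokens)
    if len(factors) != len(tokens) or not 1 <= len(factors) <= 2:
        raise ValueError(f"cannot parse condition label {label!r}")
    kind = KIND_SINGLE if len(factors) == 1 else KIND_PAIR
    return Condition(factors, with_ef, kind)


@dataclass
class ConditionCatalog:
    """The full condition list of a screen plus the with/without-E&F pairing."""

    conditions: list[Condition] = field(default_factory=list)

    def __post_init__(self) -> None:
        labels = [c.label for c in self.conditions]
        if len(set(labels)) != len(labels):
            raise ValueError("duplicate condition labels in catalog")

    @cached_property
    def labels(self) -> list[str]:
        return [c.label for c in self.conditions]

    @cached_property
    def by_label(self) -> dict[str, Condition]:
        return {c.label: c for c in self.conditions}

    @cached_property
    def non_control(self) -> list[Condition]:
        return [c for c in self.conditions if not c.is_control]

    @cached_property
    def ef_pairing(self) -> dict[str, str]:
        """Map from each non-control without-E&F condition label to its
        with-E&F twin's label (a bijection between the two halves)."""
        without = {c.factors: c for c in self.non_control if not c.with_ef}
        with_ef = {c.factors: c for c in self.non_control if c.with_ef}
        if set(without) != set(with_ef):
            raise ValueError("with/without-E&F halves of the catalog do not pair up")
        return {without[f].label: with_ef[f].label for f in without}

    def __len__(self) -> int:
        return len(self.conditions)


def enumerate_conditions(panel=DEFAULT_PANEL) -> ConditionCatalog:
    """Enumerate the full screening catalog for a panel.

    Requires exactly two basal factors (EGF and bFGF); every single candidate
    factor and every unordered candidate pair appears once with and once
    without E&F, plus the NO_GF and NBE controls.
    """
    ids = [gf.id for gf in panel]
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate growth factor ids in panel")
    basal = [gf for gf in panel if gf.is_basal]
    if len(basal) != 2:
        raise ValueError(f"panel must contain exactly 2 basal factors, got {len(basal)}")
    candidates = _sorted_factors(gf.id for gf in panel if not gf.is_basal)

    conditions: list[Condition] = [
        Condition(frozenset(), False, KIND_CONTROL_NO_GF),
        Condition(frozenset(), True, KIND_CONTROL_NBE),
    ]
    combos: list[frozenset[str]] = [frozenset({f}) for f in candidates]
    combos += [frozenset(p) for p in itertools.combinations(candidates, 2)]
    non_control = []
    for fac in combos:
        kind = KIND_SINGLE if len(fac) == 1 else KIND_PAIR
        non_control.append(Condition(fac, False, kind))
        non_control.append(Condition(fac, True, kind))
    non_control.sort(key=lambda c: c.label.lower())
    conditions.extend(non_control)
    catalog = ConditionCatalog(conditions)
    catalog.ef_pairing  # validate the bijection eagerly
    m = len(candidates)
    expected = 2 * (math.comb(m, 2) + m)
    if len(catalog.non_control) != expected:
        raise AssertionError("condition count law violated")
    return catalog


_PLATE_ROWS = "ABCDEFGHIJKLMNOP"
_PLATE_COLS = 24
_WELLS_PER_PLATE = len(_PLATE_ROWS) * _PLATE_COLS


def plate_layout(catalog: ConditionCatalog, n_replicates: int = 2) -> pd.DataFrame:
    """Assign every condition x replicate to a well on 384-well plates.

    Fill order is row-major (A01, A02, ... A24, B01, ...) following catalog
    order with replicates adjacent; a new plate is started every 384 wells.
    """
    if n_replicates < 1:
        raise ValueError("n_replicates must be >= 1")
    rows = []
    i = 0
    for cond in catalog.conditions:
        for rep in range(1, n_replicates + 1):
            plate, offset = divmod(i, _WELLS_PER_PLATE)
            r, col = divmod(offset, _PLATE_COLS)
            rows.append(
                {
                    "plate": plate + 1,
                    "well": f"{_PLATE_ROWS[r]}{col + 1:02d}",
                    "condition_id": cond.label,
                    "replicate": rep,
                }
            )
            i += 1
    return pd.DataFrame(rows)
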