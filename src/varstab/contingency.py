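"""Threshold and contingency analyses over annotated variant tables.

These reproduce the study's count claims linking predicted stability
(ddG), measured steady-state abundance, functional class (DME), and
ClinVar annotation: e.g. "of the variants with ddG > 3 kcal/mol, how many
have steady-state below 75% of wild type". Records missing a referenced
field are excluded from that predicate's universe; censored ddG values
participate at the truncation ceiling (15 kcal/mol) and therefore satisfy
every threshold at or below it.
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass
from typing import Callable

import numpy as np

from .variants import VariantRecord, VariantTable

__all__ = [
    "Predicate",
    "ContingencyResult",
    "dme_group",
    "threshold_counts",
    "class_summary",
    "fishtail_data",
    "landscape_assign",
    "parse_predicate",
]

_FIELD_GETTERS: dict[str, Callable[[VariantRecord], float | None]] = {
    "ddg": lambda r: r.ddg,
    "steady_state": lambda r: r.steady_state,
    "dme": lambda r: r.dme,
    "evo_energy": lambda r: r.evo_energy,
    "allele_freq": lambda r: r.allele_freq,
}

_COMPARATORS: dict[str, Callable[[float, float], bool]] = {
    "<": lambda v, t: v < t,
    "<=": lambda v, t: v <= t,
    ">": lambda v, t: v > t,
    ">=": lambda v, t: v >= t,
    "=": lambda v, t: v == t,
}


@dataclass(frozen=True)
class Predicate:
    """field <comparator> threshold, e.g. ``ddg > 3``."""

    field: str
    comparator: str
    threshold: float

    def __post_init__(self) -> None:
        if self.field not in _FIELD_GETTERS:
            raise KeyError(
                f"unknown field {self.field!r}; known: {sorted(_FIELD_GETTERS)}"
            )
        if self.comparator not in _COMPARATORS:
            raise ValueError(f"unknown comparator {self.comparator!r}")

    def value(self, record: VariantRecord) -> float | None:
        return _FIELD_GETTERS[self.field](record)

    def __call__(self, record: VariantRecord) -> bool | None:
        """True/False, or None when the field is NA for this record."""
        v = self.value(record)
        if v is None:
            return None
        return _COMPARATORS[self.comparator](float(v), self.threshold)

    def __str__(self) -> str:
        return f"{self.field}{self.comparator}{self.threshold:g}"


_PRED_RE = re.compile(r"^\s*(\w+)\s*(<=|>=|<|>|=)\s*(-?[\d.]+)\s*$")


def parse_predicate(text: str) -> Predicate:
    """Parse the tiny predicate grammar: ``field (<|<=|>|>=|=) number``."""
    m = _PRED_RE.match(text)
    if m is None:
        raise ValueError(f"cannot parse predicate {text!r}")
    return Predicate(m.group(1), m.group(2), float(m.group(3)))


@dataclass
class ContingencyResult:
    """2x2 counts for a (select, among) predicate pair.

    The universe is the set of records with both fields present;
    ``n_select`` of those satisfy ``select``, and ``n_both`` additionally
    satisfy ``among`` — the printed "n_both / n_select" convention.
    """

    select: Predicate
    among: Predicate
    n_both: int
    n_select: int
    n_among: int
    n_universe: int

    @property
    def counts(self) -> tuple[tuple[int, int], tuple[int, int]]:
        a = self.n_both
        b = self.n_select - self.n_both
        c = self.n_among - self.n_both
        d = self.n_universe - self.n_select - self.n_among + self.n_both
        return ((a, b), (c, d))


def dme_group(assay_flags: tuple[bool, bool, bool]) -> int:
    """Number of the three functional assays the variant passed (0-3)."""
    if len(assay_flags) != 3:
        raise ValueError("exactly three assay outcomes required")
    return sum(bool(f) for f in assay_flags)


def threshold_counts(
    table: VariantTable,
    select: Predicate | str,
    among: Predicate | str,
) -> ContingencyResult:
    """Count records satisfying ``among`` within those satisfying ``select``.

    Records with NA in either referenced field are excluded from the
    universe; both predicates see censored ddG as 15.0.
    """
    if isinstance(select, str):
        select = parse_predicate(select)
    if isinstance(among, str):
        among = parse_predicate(among)
    n_both = n_select = n_among = n_universe = 0
    for r in table:
        s, a = select(r), among(r)
        if s is None or a is None:
            continue
        n_universe += 1
        n_select += s
        n_among += a
        n_both += s and a
    return ContingencyResult(select, among, n_both, n_select, n_among, n_universe)


def class_summary(
    table: VariantTable,
    group_field: str = "dme",
    value_field: str = "steady_state",
) -> dict:
    """Per-group n, mean, and standard error of the mean of a value field.

    NA values are excluded; SEM = sd / sqrt(n) (sample sd), NA when n < 2.
    """
    get_group = _FIELD_GETTERS.get(group_field) or (
        (lambda r: r.clinvar_class) if group_field == "clinvar_class" else None
    )
    if get_group is None:
        raise KeyError(f"unknown group field {group_field!r}")
    get_value = _FIELD_GETTERS[value_field]
    groups: dict = {}
    for r in table:
        g, v = get_group(r), get_value(r)
        if g is None or v is None:
            continue
        groups.setdefault(g, []).append(float(v))
    out = {}
    for g in sorted(groups):
        vals = np.asarray(groups[g])
        sem = float(vals.std(ddof=1) / math.sqrt(len(vals))) if len(vals) > 1 else None
        out[g] = {"n": len(vals), "mean": float(vals.mean()), "sem": sem}
    return out


def fishtail_data(table: VariantTable) -> dict:
    """Allele-frequency vs ddG pairs, with an explicit zero-frequency lane.

    Records with frequency exactly 0 ("seen in patients, absent from the
    population database") are a separate lane; positive frequencies carry
    a log10 coordinate. Records missing either field are counted, never
    silently dropped.
    """
    zero_lane, points, n_excluded = [], [], 0
    for r in table:
        if r.allele_freq is None or r.ddg is None:
            n_excluded += 1
            continue
        if r.allele_freq < 0:
            raise ValueError(f"negative allele frequency for {r.name}")
        if r.allele_freq == 0:
            zero_lane.append((r.name, r.ddg))
        else:
            points.append((r.name, r.allele_freq, math.log10(r.allele_freq), r.ddg))
    return {"zero_lane": zero_lane, "points": points, "n_excluded": n_excluded}


def landscape_assign(
    table: VariantTable,
    ddg_threshold: float = 3.0,
    evo_threshold: float = 0.5,
) -> dict[str, str]:
    """Quadrant label per record in the (ddG, evo energy) plane.

    Upper-right (both strictly above threshold) is the most likely
    detrimental corner; lower-left the tolerated one. A record exactly at
    a threshold falls on the lower/left side.
    """
    labels = {}
    for r in table:
        if r.ddg is None or r.evo_energy is None:
            continue
        high_ddg = r.ddg > ddg_threshold
        high_evo = r.evo_energy > evo_threshold
        if high_ddg and high_evo:
            lab = "detrimental"
        elif high_ddg:
            lab = "destabilized_only"
        elif high_evo:
            lab = "conserved_only"
        else:
            lab = "tolerated"
        labels[r.name] = lab
    return labels
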