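"""Saturation-mutagenesis ddG handling.

In silico saturation mutagenesis enumerates all 19 non-wild-type amino-acid
substitutions at every structurally modeled residue. Per-variant stability
changes (ddG, kcal/mol; positive = destabilizing) arrive as replicate
prediction runs which are averaged and then truncated at a ceiling (default
15 kcal/mol) above which the underlying force field mostly reports clashes
rather than meaningful magnitudes.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from pathlib import Path
from typing import Sequence

import numpy as np

from .variants import AMINO_ACIDS, VariantTable, parse_variant_name

__all__ = [
    "DomainDefinition",
    "DdgMatrix",
    "enumerate_saturation",
    "coverage_fraction",
    "aggregate_replicates",
    "truncate_ddg",
    "stability_fractions",
    "parse_replicate_table",
    "annotate_table",
]

DEFAULT_CAP = 15.0


@dataclass(frozen=True)
class DomainDefinition:
    """Inclusive 1-based residue intervals of the structurally modeled domains."""

    ranges: tuple[tuple[int, int], ...]
    name: str = ""

    def __post_init__(self) -> None:
        prev_end = 0
        for start, end in self.ranges:
            if start > end:
                raise ValueError(f"interval start {start} > end {end}")
            if start <= prev_end:
                raise ValueError("intervals must be sorted and non-overlapping")
            prev_end = end

    @property
    def positions(self) -> list[int]:
        out: list[int] = []
        for start, end in self.ranges:
            out.extend(range(start, end + 1))
        return out

    def __contains__(self, position: int) -> bool:
        return any(s <= position <= e for s, e in self.ranges)


#: MLH1's two folded units: N-terminal 7-315, C-terminal 502-756,
#: separated by an intrinsically disordered linker that is not modeled.
MLH1_DOMAINS = DomainDefinition(ranges=((7, 315), (502, 756)), name="MLH1")


class DdgMatrix:
    """Position x 20 amino-acid ddG map with truncation/censoring semantics.

    ``values[p][a]`` is the truncated ddG of substituting amino acid ``a``
    at position ``p``; the wild-type cell is exactly 0 and never counted as
    a substitution. ``censored[p][a]`` marks cells whose pre-truncation mean
    exceeded the cap. Unmodeled positions are simply absent.
    """

    def __init__(self, wt_by_position: dict[int, str], cap: float = DEFAULT_CAP):
        for pos, wt in wt_by_position.items():
            if wt not in AMINO_ACIDS:
                raise ValueError(f"invalid wild-type {wt!r} at position {pos}")
        self.wt = dict(sorted(wt_by_position.items()))
        self.cap = cap
        self.values: dict[int, dict[str, float]] = {
            p: {self.wt[p]: 0.0} for p in self.wt
        }
        self.censored: dict[int, set[str]] = {p: set() for p in self.wt}
        self.raw_means: dict[int, dict[str, float]] = {p: {} for p in self.wt}

    @property
    def positions(self) -> list[int]:
        return list(self.wt)

    def set(self, position: int, mut_aa: str, raw_mean: float) -> None:
        """Store an aggregated (pre-truncation) ddG; truncation is applied here."""
        if position not in self.wt:
            raise KeyError(f"position {position} not modeled")
        if mut_aa == self.wt[position]:
            raise ValueError("wild-type cell is fixed at 0")
        self.raw_means[position][mut_aa] = raw_mean
        self.values[position][mut_aa] = truncate_ddg(raw_mean, self.cap)
        if raw_mean > self.cap:
            self.censored[position].add(mut_aa)

    def get(self, position: int, mut_aa: str) -> float | None:
        """Truncated ddG, or None where unmodeled/unfilled."""
        return self.values.get(position, {}).get(mut_aa)

    def is_censored(self, position: int, mut_aa: str) -> bool:
        return mut_aa in self.censored.get(position, set())

    def substitution_values(self) -> np.ndarray:
        """All filled non-wild-type cells as a flat array."""
        vals = [
            v
            for p, row in self.values.items()
            for a, v in row.items()
            if a != self.wt[p]
        ]
        return np.asarray(vals, dtype=float)

    def to_long_frame(self):
        """Long-format export: position, wt, mut, ddg, censored."""
        import pandas as pd

        rows = []
        for p in self.positions:
            wt = self.wt[p]
            for a in AMINO_ACIDS:
                if a == wt:
                    continue
                v = self.values[p].get(a)
                if v is None:
                    continue
                rows.append(
                    {
                        "position": p,
                        "wt": wt,
                        "mut": a,
                        "ddg": v,
                        "censored": a in self.censored[p],
                    }
                )
        return pd.DataFrame(rows)


def enumerate_saturation(
    domains: DomainDefinition, sequence: str
) -> list[tuple[int, str, str]]:
    """All 19 substitutions at every in-domain residue of ``sequence``.

    Positions are 1-based; raises if a domain interval exceeds the sequence.
    """
    for start, end in domains.ranges:
        if end > len(sequence) or start < 1:
            raise IndexError(
                f"domain interval ({start},{end}) outside sequence of length {len(sequence)}"
            )
    out = []
    for pos in domains.positions:
        wt = sequence[pos - 1]
        if wt not in AMINO_ACIDS:
            raise ValueError(f"invalid residue {wt!r} at position {pos}")
        for mut in AMINO_ACIDS:
            if mut != wt:
                out.append((pos, wt, mut))
    return out


def coverage_fraction(domains: DomainDefinition, sequence_length: int) -> float:
    """Percent of all possible missense variants covered by the domains.

    100 * 19*(in-range residues) / (19*L) — the 19s cancel but both counts
    are stated in variant units for clarity.
    """
    if sequence_length <= 0:
        raise ValueError("sequence length must be positive")
    n_in = len(domains.positions)
    return 100.0 * (19 * n_in) / (19 * sequence_length)


def aggregate_replicates(replicate_values: Sequence[float]) -> float:
    """Arithmetic mean over replicate prediction runs (before truncation)."""
    if len(replicate_values) == 0:
        raise ValueError("need at least one replicate")
    return float(np.mean(replicate_values))


def truncate_ddg(value: float, cap: float = DEFAULT_CAP) -> float:
    """min(value, cap); idempotent, leaves stabilizing (negative) values alone."""
    return min(float(value), cap)


def stability_fractions(
    matrix: DdgMatrix, low: float = 0.7, high: float = 2.5
) -> tuple[float, float]:
    """Share of substitutions with |ddG| < ``low`` and with ddG > ``high``.

    The low bin uses the absolute value (the prediction error band is
    symmetric); both comparisons are strict.
    """
    vals = matrix.substitution_values()
    if vals.size == 0:
        raise ValueError("matrix has no filled substitution entries")
    frac_low = float(np.mean(np.abs(vals) < low))
    frac_high = float(np.mean(vals > high))
    return frac_low, frac_high


def parse_replicate_table(path: str | Path, cap: float = DEFAULT_CAP) -> DdgMatrix:
    """Build a :class:`DdgMatrix` from a (variant, replicate, ddg) TSV.

    Replicates per variant are averaged, then truncated at ``cap``.
    Wild-type letters are taken from the variant names and checked for
    consistency across rows.
    """
    groups: dict[tuple[int, str, str], list[float]] = {}
    wt_claim: dict[int, str] = {}
    with open(path, encoding="utf-8") as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if header[:3] != ["variant", "replicate", "ddg_kcal_mol"]:
            raise ValueError(
                f"{path}: expected header variant/replicate/ddg_kcal_mol, got {header}"
            )
        for lineno, line in enumerate(fh, start=2):
            if not line.strip():
                continue
            name, _rep, raw = line.rstrip("\n").split("\t")[:3]
            wt, pos, mut = parse_variant_name(name)
            if wt_claim.setdefault(pos, wt) != wt:
                raise ValueError(
                    f"{path}:{lineno}: conflicting wild-type at position {pos}: "
                    f"{wt_claim[pos]} vs {wt}"
                )
            groups.setdefault((pos, wt, mut), []).append(float(raw))
    matrix = DdgMatrix(wt_claim, cap=cap)
    for (pos, _wt, mut), reps in groups.items():
        matrix.set(pos, mut, aggregate_replicates(reps))
    return matrix


def annotate_table(table: VariantTable, matrix: DdgMatrix) -> VariantTable:
    """Fill each record's ddG from the matrix; leave NA where unmodeled.

    Raises if the matrix claims a different wild-type residue at a position
    the table also covers.
    """
    out = []
    for r in table:
        if r.position in matrix.wt and matrix.wt[r.position] != r.wt_aa:
            raise ValueError(
                f"wild-type mismatch at position {r.position}: table says "
                f"{r.wt_aa}, matrix says {matrix.wt[r.position]}"
            )
        v = matrix.get(r.position, r.mut_aa)
        if v is None:
            out.append(r)
        else:
            out.append(
                replace(
                    r,
                    ddg=v,
                    ddg_censored=matrix.is_censored(r.position, r.mut_aa),
                )
            )
    return table.replace_records(out)
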