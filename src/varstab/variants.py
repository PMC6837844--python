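"""Variant data model and tabular IO.

A variant is a single amino-acid substitution named in the conventional
``<wt><position><mut>`` form (e.g. ``G67R``), with 1-based positions in the
query protein's numbering. Records carry the quantities the downstream
analyses consume: a predicted stability change (ddG, kcal/mol, possibly
censored at a truncation ceiling), a measured steady-state abundance
(percent of wild type), a ClinVar classification, a 0-3 functional class
(dominant mutator effect, DME), evolutionary sequence energies (raw and
rank-normalized), and a population allele frequency.

The packaged fixture table holds the 69 experimentally characterized MLH1
missense variants (UniProt P40692-1 numbering) used throughout the analysis.
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass, field, replace
from importlib import resources
from pathlib import Path
from typing import Iterable, Iterator

__all__ = [
    "AMINO_ACIDS",
    "CLINVAR_CLASSES",
    "VariantRecord",
    "VariantTable",
    "VariantParseError",
    "VariantTableError",
    "parse_variant_name",
    "format_variant_name",
    "clinvar_binary_label",
    "read_variant_tsv",
    "write_variant_tsv",
    "load_fixture_table",
]

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"

CLINVAR_CLASSES = frozenset(
    {"benign", "likely_benign", "VUS", "likely_pathogenic", "pathogenic"}
)

#: ddG ceiling above which source tables print a lower bound (">15").
DDG_CAP = 15.0

_NAME_RE = re.compile(r"^([A-Za-z])(\d+)([A-Za-z])$")

# aliases seen in hand-edited tables
_CLASS_ALIASES = {
    "(likely) pathogenic": "likely_pathogenic",
    "(likely) benign": "likely_benign",
    "vus": "VUS",
}


class VariantParseError(ValueError):
    """A variant name or field value could not be parsed."""


class VariantTableError(ValueError):
    """A table violates a structural invariant (duplicates, bad columns)."""


def parse_variant_name(name: str) -> tuple[str, int, str]:
    """Parse ``G67R`` into ``("G", 67, "R")``.

    Raises :class:`VariantParseError` for malformed strings, non-standard
    amino-acid letters, or synonymous (wt == mut) names.
    """
    m = _NAME_RE.match(name.strip())
    if m is None:
        raise VariantParseError(f"malformed variant name: {name!r}")
    wt, pos, mut = m.group(1).upper(), int(m.group(2)), m.group(3).upper()
    for token in (wt, mut):
        if token not in AMINO_ACIDS:
            raise VariantParseError(
                f"non-standard amino acid {token!r} in variant name {name!r}"
            )
    if pos < 1:
        raise VariantParseError(f"position must be >= 1 in {name!r}")
    if wt == mut:
        raise VariantParseError(f"synonymous variant (wt == mut): {name!r}")
    return wt, pos, mut


def format_variant_name(wt_aa: str, position: int, mut_aa: str) -> str:
    """Inverse of :func:`parse_variant_name`."""
    return f"{wt_aa}{position}{mut_aa}"


@dataclass
class VariantRecord:
    """One missense variant and its annotations. ``None`` encodes NA."""

    position: int
    wt_aa: str
    mut_aa: str
    ddg: float | None = None
    ddg_censored: bool = False
    steady_state: float | None = None
    clinvar_class: str | None = None
    dme: int | None = None
    evo_energy: float | None = None
    evo_raw: float | None = None
    allele_freq: float | None = None
    #: unknown input columns preserved verbatim (e.g. REVEL/PolyPhen2 scores)
    extras: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.wt_aa not in AMINO_ACIDS or self.mut_aa not in AMINO_ACIDS:
            raise VariantParseError(
                f"non-standard amino acid in {self.wt_aa}{self.position}{self.mut_aa}"
            )
        if self.mut_aa == self.wt_aa:
            raise VariantParseError(
                f"synonymous record at position {self.position}: {self.wt_aa}"
            )
        if self.position < 1:
            raise VariantParseError("positions are 1-based; got %d" % self.position)
        if self.ddg_censored and (self.ddg is None or self.ddg != DDG_CAP):
            raise VariantParseError(
                f"censored ddG must equal the cap {DDG_CAP}, got {self.ddg}"
            )
        if self.steady_state is not None and self.steady_state < 0:
            raise VariantParseError("steady_state must be >= 0")
        if self.clinvar_class is not None and self.clinvar_class not in CLINVAR_CLASSES:
            raise VariantParseError(f"unknown ClinVar class {self.clinvar_class!r}")
        if self.dme is not None and self.dme not in (0, 1, 2, 3):
            raise VariantParseError(f"DME must be 0-3, got {self.dme}")
        if self.evo_energy is not None and not 0.0 < self.evo_energy < 1.0:
            raise VariantParseError("evo_energy must lie strictly in (0,1)")
        if self.allele_freq is not None and not 0.0 <= self.allele_freq <= 1.0:
            raise VariantParseError("allele_freq must lie in [0,1]")

    @property
    def name(self) -> str:
        return format_variant_name(self.wt_aa, self.position, self.mut_aa)

    @property
    def key(self) -> tuple[int, str, str]:
        return (self.position, self.wt_aa, self.mut_aa)


class VariantTable:
    """Ordered, duplicate-free collection of :class:`VariantRecord`."""

    def __init__(self, records: Iterable[VariantRecord], provenance: str = ""):
        self.records: list[VariantRecord] = list(records)
        self.provenance = provenance
        seen: set[tuple[int, str, str]] = set()
        for r in self.records:
            if r.key in seen:
                raise VariantTableError(f"duplicate variant {r.name}")
            seen.add(r.key)

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self) -> Iterator[VariantRecord]:
        return iter(self.records)

    def __getitem__(self, name: str) -> VariantRecord:
        wt, pos, mut = parse_variant_name(name)
        for r in self.records:
            if r.key == (pos, wt, mut):
                return r
        raise KeyError(name)

    def replace_records(self, records: Iterable[VariantRecord]) -> "VariantTable":
        return VariantTable(records, provenance=self.provenance)

    def to_frame(self):
        """Materialize as a :class:`pandas.DataFrame` (NA as NaN/None)."""
        import pandas as pd

        rows = []
        for r in self.records:
            row = {
                "variant": r.name,
                "steady_state_pct": r.steady_state,
                "ddg_kcal_mol": r.ddg,
                "ddg_censored": r.ddg_censored,
                "clinvar_class": r.clinvar_class,
                "dme": r.dme,
                "evo_energy": r.evo_energy,
                "evo_raw": r.evo_raw,
                "allele_freq": r.allele_freq,
            }
            row.update(r.extras)
            rows.append(row)
        return pd.DataFrame(rows)


def clinvar_binary_label(clinvar_class: str | None) -> str:
    """Collapse the five-level ClinVar scale to a training label.

    (Likely) pathogenic -> ``"positive"``, (likely) benign -> ``"negative"``,
    VUS and missing -> ``"excluded"``.
    """
    if clinvar_class is None:
        return "excluded"
    if clinvar_class not in CLINVAR_CLASSES:
        raise VariantParseError(f"unknown ClinVar class {clinvar_class!r}")
    if clinvar_class in ("pathogenic", "likely_pathogenic"):
        return "positive"
    if clinvar_class in ("benign", "likely_benign"):
        return "negative"
    return "excluded"


_CORE_COLUMNS = (
    "variant",
    "steady_state_pct",
    "ddg_kcal_mol",
    "clinvar_class",
    "dme",
    "evo_energy",
    "evo_raw",
    "allele_freq",
)


def _parse_float(token: str) -> float | None:
    token = token.strip()
    if token in ("", ".", "NA", "nan"):
        return None
    # unicode minus appears in transcribed tables
    return float(token.replace("−", "-"))


def read_variant_tsv(path: str | Path, provenance: str | None = None) -> VariantTable:
    """Read a tab-separated variant table.

    The only mandatory column is ``variant``; every core column that is
    absent maps to NA, unknown columns are preserved as pass-through
    annotations. ``">15"`` in the ddG column marks a censored value stored
    as 15.0 with the censored flag set; ``"."``/empty/``NA`` encode missing.
    """
    path = Path(path)
    with open(path, encoding="utf-8") as fh:
        header_line = fh.readline().rstrip("\n")
        if not header_line:
            raise VariantTableError(f"{path}: empty file")
        header = header_line.split("\t")
        if "variant" not in header:
            missing = sorted({"variant"} - set(header))
            raise VariantTableError(f"{path}: missing mandatory columns {missing}")
        extra_cols = [c for c in header if c not in _CORE_COLUMNS]
        records = []
        for lineno, line in enumerate(fh, start=2):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) != len(header):
                raise VariantTableError(
                    f"{path}:{lineno}: expected {len(header)} fields, got {len(fields)}"
                )
            row = dict(zip(header, fields))
            wt, pos, mut = parse_variant_name(row["variant"])
            ddg, censored = None, False
            raw_ddg = row.get("ddg_kcal_mol", "").strip()
            if raw_ddg.startswith(">"):
                ddg, censored = float(raw_ddg[1:]), True
            else:
                ddg = _parse_float(raw_ddg) if "ddg_kcal_mol" in row else None
            clin = row.get("clinvar_class", "").strip()
            if clin in (".", "NA"):
                clin = ""
            clin = _CLASS_ALIASES.get(clin.lower(), _CLASS_ALIASES.get(clin, clin))
            dme_val = _parse_float(row.get("dme", ""))
            extras = {c: row[c] for c in extra_cols if c != "variant"}
            records.append(
                VariantRecord(
                    position=pos,
                    wt_aa=wt,
                    mut_aa=mut,
                    ddg=ddg,
                    ddg_censored=censored,
                    steady_state=_parse_float(row.get("steady_state_pct", "")),
                    clinvar_class=clin or None,
                    dme=int(dme_val) if dme_val is not None else None,
                    evo_energy=_parse_float(row.get("evo_energy", "")),
                    evo_raw=_parse_float(row.get("evo_raw", "")),
                    allele_freq=_parse_float(row.get("allele_freq", "")),
                    extras=extras,
                )
            )
    return VariantTable(records, provenance=provenance or str(path))


def _fmt(value, censored: bool = False) -> str:
    if censored:
        return f">{DDG_CAP:g}"
    if value is None:
        return "."
    if isinstance(value, bool):
        return str(value)
    if isinstance(value, float):
        if math.isnan(value):
            return "."
        return f"{value:g}"
    return str(value)


def write_variant_tsv(table: VariantTable, path: str | Path) -> None:
    """Write a table in the dialect :func:`read_variant_tsv` reads back."""
    extra_cols: list[str] = []
    for r in table:
        for c in r.extras:
            if c not in extra_cols:
                extra_cols.append(c)
    header = list(_CORE_COLUMNS) + extra_cols
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("\t".join(header) + "\n")
        for r in table:
            row = [
                r.name,
                _fmt(r.steady_state),
                _fmt(r.ddg, r.ddg_censored),
                _fmt(r.clinvar_class),
                _fmt(r.dme),
                _fmt(r.evo_energy),
                _fmt(r.evo_raw),
                _fmt(r.allele_freq),
            ]
            row += [str(r.extras.get(c, ".")) for c in extra_cols]
            fh.write("\t".join(row) + "\n")


def load_fixture_table() -> VariantTable:
    """Load the packaged 69-variant MLH1 fixture table.

    Performs integrity checks: exactly 69 records, every record annotated
    with steady-state level, ddG and ClinVar class, and DME missing only
    for I36S.
    """
    ref = resources.files("varstab.data").joinpath("mlh1_panel69.tsv")
    with resources.as_file(ref) as p:
        table = read_variant_tsv(p, provenance="mlh1_panel69")
    if len(table) != 69:
        raise VariantTableError(
            f"fixture corrupted: expected 69 records, found {len(table)}"
        )
    for r in table:
        if r.steady_state is None or r.ddg is None or r.clinvar_class is None:
            raise VariantTableError(f"fixture corrupted: incomplete record {r.name}")
        if r.dme is None and r.name != "I36S":
            raise VariantTableError(f"fixture corrupted: unexpected NA DME for {r.name}")
    return table
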