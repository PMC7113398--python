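"""HLA allele nomenclature: parsing, validation, and two-digit collapsing.

The six classical loci handled here are HLA-A, -B, -C (class I) and
HLA-DPB1, -DQB1, -DRB1 (class II).  A four-digit allele name such as
``HLA-A*01:01`` consists of the gene, an allele-group field ("field1",
historically the serological antigen group) and a protein-level field
("field2"), joined by ``*`` and ``:``.  Because individual four-digit
alleles are rare in any one cohort, association work pools them into
their allele group — the two-digit "superallele" ``HLA-A*01`` — by
dropping field2.

Field strings are preserved verbatim (IMGT names are zero-padded text),
but equality and ordering compare fields numerically, so ``A*1`` and
``A*01`` denote the same allele group while formatting never invents or
drops padding.  Expression-level suffixes (``N``, ``L`` ...) and fields
beyond field2 are rejected rather than silently truncated.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping

__all__ = [
    "GENES",
    "CLASS_I",
    "CLASS_II",
    "AlleleName",
    "Superallele",
    "AlleleParseError",
    "parse_allele",
    "to_superallele",
    "collapse_allele_table",
    "summarize_collapse",
    "read_allele_list",
    "superallele_sort_key",
]

GENES: tuple[str, ...] = ("A", "B", "C", "DPB1", "DQB1", "DRB1")
CLASS_I = frozenset({"A", "B", "C"})
CLASS_II = frozenset({"DPB1", "DQB1", "DRB1"})


class AlleleParseError(ValueError):
    """Raised when an HLA allele string violates the naming grammar."""


_NAME_RE = re.compile(r"^(?:HLA-)?(?P<gene>[A-Z]+\d*)\*(?P<fields>.+)$", re.IGNORECASE)


@dataclass(frozen=True)
class AlleleName:
    """A typed HLA allele at two- or four-digit resolution.

    ``field2`` is ``None`` for names already given at allele-group
    (two-digit) resolution.
    """

    gene: str
    field1: str
    field2: str | None = None

    def __post_init__(self) -> None:
        if self.gene not in GENES:
            raise AlleleParseError(f"unknown HLA gene {self.gene!r}; expected one of {GENES}")
        if not self.field1 or not self.field1.isdigit():
            raise AlleleParseError(f"field1 {self.field1!r} is not a digit string")
        if self.field2 is not None and (not self.field2 or not self.field2.isdigit()):
            raise AlleleParseError(f"field2 {self.field2!r} is not a digit string")

    @property
    def hla_class(self) -> str:
        return "I" if self.gene in CLASS_I else "II"

    def __str__(self) -> str:
        if self.field2 is None:
            return f"HLA-{self.gene}*{self.field1}"
        return f"HLA-{self.gene}*{self.field1}:{self.field2}"

    # numeric comparison so "01" == "1"; formatting keeps the original text
    def _key(self) -> tuple:
        return (
            self.gene,
            int(self.field1),
            -1 if self.field2 is None else int(self.field2),
        )

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, AlleleName):
            return NotImplemented
        return self._key() == other._key()

    def __hash__(self) -> int:
        return hash(self._key())

    def __lt__(self, other: "AlleleName") -> bool:
        return (GENES.index(self.gene), int(self.field1),
                -1 if self.field2 is None else int(self.field2)) < (
                GENES.index(other.gene), int(other.field1),
                -1 if other.field2 is None else int(other.field2))


@dataclass(frozen=True)
class Superallele:
    """An allele group: a gene plus field1 only (e.g. ``HLA-A*01``)."""

    gene: str
    field1: str

    def __post_init__(self) -> None:
        if self.gene not in GENES:
            raise AlleleParseError(f"unknown HLA gene {self.gene!r}; expected one of {GENES}")
        if not self.field1 or not self.field1.isdigit():
            raise AlleleParseError(f"field1 {self.field1!r} is not a digit string")

    @property
    def hla_class(self) -> str:
        return "I" if self.gene in CLASS_I else "II"

    def __str__(self) -> str:
        return f"HLA-{self.gene}*{self.field1}"

    def _key(self) -> tuple:
        return (self.gene, int(self.field1))

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, Superallele):
            return NotImplemented
        return self._key() == other._key()

    def __hash__(self) -> int:
        return hash(self._key())

    def __lt__(self, other: "Superallele") -> bool:
        return superallele_sort_key(self) < superallele_sort_key(other)


def superallele_sort_key(sa: Superallele) -> tuple[int, int]:
    """Deterministic column order: gene (A,B,C,DPB1,DQB1,DRB1), then numeric field1."""
    return (GENES.index(sa.gene), int(sa.field1))


def parse_allele(text: str) -> AlleleName:
    """Parse an HLA allele name at two- or four-digit resolution.

    Accepts both ``HLA-A*01:01`` and ``A*01:01`` spellings.  Raises
    :class:`AlleleParseError` naming the offending token on a malformed
    separator, unknown gene, non-digit field, or an expression-level
    suffix / extra field beyond field2.
    """
    if not text or not text.strip():
        raise AlleleParseError("empty allele name")
    text = text.strip()
    m = _NAME_RE.match(text)
    if m is None:
        raise AlleleParseError(
            f"malformed allele name {text!r}: expected '<gene>*<field1>[:<field2>]' "
            "(missing or misplaced '*' separator)"
        )
    gene = m.group("gene").upper()
    if gene not in GENES:
        raise AlleleParseError(f"unknown HLA gene {gene!r} in {text!r}; expected one of {GENES}")
    fields = m.group("fields").split(":")
    if len(fields) > 2:
        raise AlleleParseError(
            f"allele {text!r} has {len(fields)} fields; only field1[:field2] is supported"
        )
    for f in fields:
        if not f or not f.isdigit():
            raise AlleleParseError(
                f"non-digit field {f!r} in {text!r} (expression suffixes are not supported)"
            )
    field1 = fields[0]
    field2 = fields[1] if len(fields) == 2 else None
    return AlleleName(gene=gene, field1=field1, field2=field2)


def to_superallele(a: AlleleName | Superallele) -> Superallele:
    """Collapse an allele name to its allele group (drop field2).

    Idempotent: a two-digit name maps to the identically named
    superallele.
    """
    if isinstance(a, Superallele):
        return a
    return Superallele(gene=a.gene, field1=a.field1)


def collapse_allele_table(
    alleles: Iterable[str],
) -> dict[Superallele, set[AlleleName]]:
    """Group a list of allele strings by superallele.

    Returns a mapping from each superallele to the set of distinct
    four-/two-digit alleles observed under it.  Parse errors are
    re-raised with the (0-based) row index of the offending entry.
    """
    out: dict[Superallele, set[AlleleName]] = {}
    for i, text in enumerate(alleles):
        try:
            name = parse_allele(text)
        except AlleleParseError as exc:
            raise AlleleParseError(f"row {i}: {exc}") from exc
        out.setdefault(to_superallele(name), set()).add(name)
    return out


def summarize_collapse(mapping: Mapping[Superallele, set[AlleleName]]) -> dict[str, int]:
    """Counts of distinct alleles and superalleles, overall and per class."""
    n_alleles = sum(len(v) for v in mapping.values())
    n_super = len(mapping)
    n_super_1 = sum(1 for sa in mapping if sa.hla_class == "I")
    n_alleles_1 = sum(len(v) for sa, v in mapping.items() if sa.hla_class == "I")
    return {
        "n_alleles": n_alleles,
        "n_superalleles": n_super,
        "n_superalleles_class_I": n_super_1,
        "n_superalleles_class_II": n_super - n_super_1,
        "n_alleles_class_I": n_alleles_1,
        "n_alleles_class_II": n_alleles - n_alleles_1,
    }


def read_allele_list(path: str | Path) -> list[AlleleName]:
    """Read a one-allele-per-line UTF-8 file; '#' lines are comments."""
    names: list[AlleleName] = []
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            try:
                names.append(parse_allele(line))
            except AlleleParseError as exc:
                raise AlleleParseError(f"{path}:{lineno}: {exc}") from exc
    return names
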