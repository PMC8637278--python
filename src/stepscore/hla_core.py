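"""HLA domain types, typing parsers, and mismatch counting.

The package works with two resolutions of HLA typing:

* serological ("broad antigen") typing — one or two labels per locus
  *group* (A, B, C, DR, DQ, DP), e.g. ``A1;A2``.  This is the resolution
  historical transplant cohorts were typed at.
* two-field ("high resolution") allele typing — one or two allele names
  per *locus*, e.g. ``DRB1*04:01``.

Mismatches are always counted in the donor → recipient direction: a donor
antigen (or eplet) mismatched to the recipient can immunize; the reverse
cannot.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

#: canonical 20-letter amino-acid alphabet, alphabetical by one-letter code
AA_ALPHABET = "ACDEFGHIKLMNPQRSTVWY"

#: loci handled by the package
LOCI = ("A", "B", "C", "DRB1", "DRB3", "DRB4", "DRB5",
        "DQA1", "DQB1", "DPA1", "DPB1")

#: serological locus group of each locus
LOCUS_GROUP: dict[str, str] = {
    "A": "A", "B": "B", "C": "C",
    "DRB1": "DR", "DRB3": "DR", "DRB4": "DR", "DRB5": "DR",
    "DQA1": "DQ", "DQB1": "DQ",
    "DPA1": "DP", "DPB1": "DP",
}

#: locus groups in canonical order
LOCUS_GROUPS = ("A", "B", "C", "DR", "DQ", "DP")

#: loci covered by eplet (B-cell epitope) counting
EPLET_LOCI = ("A", "B", "C", "DRB1", "DQB1")

_ALLELE_NAME_RE = re.compile(r"^(?P<locus>[A-Z0-9]+)\*\d{2,}:\d{2,}$")


class HlaError(Exception):
    """Base class for domain errors."""


class TypingFormatError(HlaError):
    """A typing record does not conform to the expected schema."""


class UnknownAlleleError(HlaError, LookupError):
    """An allele name is absent from the active reference."""


def locus_of(allele_name: str) -> str:
    """Extract the locus from a two-field allele name like ``DRB1*04:01``."""
    m = _ALLELE_NAME_RE.match(allele_name)
    if m is None:
        raise TypingFormatError(f"not a two-field allele name: {allele_name!r}")
    locus = m.group("locus")
    if locus not in LOCI:
        raise TypingFormatError(f"unknown locus {locus!r} in {allele_name!r}")
    return locus


@dataclass(frozen=True)
class Allele:
    """One HLA allele: identity, serological group and mature-chain protein.

    Parameters
    ----------
    locus : str
        One of :data:`LOCI`.
    name : str
        Two-field name, e.g. ``"A*01:01"``; must parse to `locus`.
    serology : str
        Serological (broad antigen) label, e.g. ``"A1"``.
    sequence : str
        Mature-chain amino-acid sequence, length >= 9, canonical residues only.
    """

    locus: str
    name: str
    serology: str
    sequence: str

    def __post_init__(self) -> None:
        if locus_of(self.name) != self.locus:
            raise TypingFormatError(
                f"allele name {self.name!r} does not parse to locus {self.locus!r}")
        if len(self.sequence) < 9:
            raise ValueError(f"{self.name}: sequence shorter than 9 residues")
        bad = set(self.sequence) - set(AA_ALPHABET)
        if bad:
            raise ValueError(f"{self.name}: non-canonical residues {sorted(bad)}")


def _normalize_labels(labels: Sequence[str], where: str) -> tuple[str, ...]:
    labels = tuple(dict.fromkeys(labels))  # homozygous -> single label
    if not 1 <= len(labels) <= 2:
        raise TypingFormatError(f"{where}: expected 1-2 labels, got {list(labels)}")
    return labels


@dataclass(frozen=True)
class SerologicalTyping:
    """Per-locus-group serological labels; A, B and DR are mandatory.

    `labels` maps a locus group ("A", "B", "C", "DR", "DQ", "DP") to a tuple
    of one or two antigen labels.  Homozygosity is encoded as a single label.
    """

    labels: Mapping[str, tuple[str, ...]]

    def __post_init__(self) -> None:
        clean: dict[str, tuple[str, ...]] = {}
        for group, labs in self.labels.items():
            if group not in LOCUS_GROUPS:
                raise TypingFormatError(f"unknown locus group {group!r}")
            clean[group] = _normalize_labels(tuple(labs), f"locus group {group}")
        missing = {"A", "B", "DR"} - clean.keys()
        if missing:
            raise TypingFormatError(f"serological typing missing required {sorted(missing)}")
        object.__setattr__(self, "labels", clean)

    @property
    def groups(self) -> tuple[str, ...]:
        return tuple(g for g in LOCUS_GROUPS if g in self.labels)

    def key(self) -> tuple:
        """Hashable canonical form (used as a cache key)."""
        return tuple((g, tuple(sorted(self.labels[g]))) for g in self.groups)


@dataclass(frozen=True)
class HighResTyping:
    """Per-locus two-field allele names (one or two per locus)."""

    alleles: Mapping[str, tuple[str, ...]]

    def __post_init__(self) -> None:
        clean: dict[str, tuple[str, ...]] = {}
        for locus, names in self.alleles.items():
            names = _normalize_labels(tuple(names), f"locus {locus}")
            for n in names:
                if locus_of(n) != locus:
                    raise TypingFormatError(f"allele {n!r} listed under locus {locus!r}")
            clean[locus] = names
        object.__setattr__(self, "alleles", clean)

    def all_alleles(self) -> tuple[str, ...]:
        return tuple(n for locus in self.alleles for n in self.alleles[locus])


@dataclass(frozen=True)
class EpletRegistry:
    """Allele name -> set of eplet identifiers, over :data:`EPLET_LOCI`."""

    eplets: Mapping[str, frozenset[str]]

    def __post_init__(self) -> None:
        object.__setattr__(
            self, "eplets", {a: frozenset(e) for a, e in self.eplets.items()})

    def eplets_of(self, allele_name: str) -> frozenset[str]:
        try:
            return self.eplets[allele_name]
        except KeyError:
            raise UnknownAlleleError(
                f"allele {allele_name!r} not in eplet registry") from None


# ---------------------------------------------------------------------------
# parsing

def _split_cell(cell: str) -> list[str]:
    return [tok.strip() for tok in str(cell).split(";") if tok.strip()]


def parse_typing(row: Mapping[str, str]) -> SerologicalTyping | HighResTyping:
    """Parse one typing-CSV row into a typing object.

    The row maps column names to cell strings; labels within a cell are
    separated by ``;``.  Resolution is auto-detected: any value containing
    ``*`` and ``:`` makes the row high-resolution, in which case every value
    must be a two-field allele name and the locus is taken from the name
    itself.  Otherwise columns are serological locus groups.  Identifier
    columns (``id``, ``role``) are ignored.
    """
    cells = {k: _split_cell(v) for k, v in row.items()
             if k not in ("id", "role") and str(v).strip() not in ("", "nan")}
    row_id = row.get("id", "<row>")
    tokens = [tok for toks in cells.values() for tok in toks]
    if not tokens:
        raise TypingFormatError(f"row {row_id}: empty typing")
    high_res = any("*" in t and ":" in t for t in tokens)
    try:
        if high_res:
            by_locus: dict[str, list[str]] = {}
            for toks in cells.values():
                for tok in toks:
                    by_locus.setdefault(locus_of(tok), []).append(tok)
            return HighResTyping(alleles={k: tuple(v) for k, v in by_locus.items()})
        return SerologicalTyping(labels={k: tuple(v) for k, v in cells.items()})
    except TypingFormatError as exc:
        raise TypingFormatError(f"row {row_id}: {exc}") from None


# ---------------------------------------------------------------------------
# mismatch counting

def count_broad_mismatches(
    donor: SerologicalTyping,
    recipient: SerologicalTyping,
    loci: Iterable[str] = ("A", "B", "DR"),
) -> int:
    """Count donor antigens absent from the recipient at the given locus groups.

    Standard antigen-level counting: per locus group, each donor label not
    carried by the recipient counts one mismatch; a homozygous donor label
    counts once.  Result is in [0, 2 * len(loci)].
    """
    total = 0
    for group in loci:
        if group not in donor.labels or group not in recipient.labels:
            raise TypingFormatError(f"locus group {group!r} missing from a typing")
        rec = set(recipient.labels[group])
        total += sum(1 for lab in donor.labels[group] if lab not in rec)
    return total


def count_eplet_mismatches(
    donor: HighResTyping,
    recipient: HighResTyping,
    registry: EpletRegistry,
) -> int:
    """HLAMatchmaker-style eplet mismatch load.

    The count is ``| union(donor eplets) - union(recipient eplets) |`` over
    the eplet-covered loci: an eplet carried by any recipient molecule never
    counts, and an eplet shared by several donor molecules counts once.
    """
    donor_eplets: set[str] = set()
    recipient_eplets: set[str] = set()
    for locus in EPLET_LOCI:
        for name in donor.alleles.get(locus, ()):
            donor_eplets |= registry.eplets_of(name)
        for name in recipient.alleles.get(locus, ()):
            recipient_eplets |= registry.eplets_of(name)
    return len(donor_eplets - recipient_eplets)
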