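"""Modified-RNA sequence model.

Sequences are written in the compact token syntax used in synthetic-guide
QC: each nucleotide is ``A``, ``C``, ``G`` or ``U``, optionally followed
by ``(m)`` for a 2'-O-methylribonucleotide or ``(ms)`` for a
2'-O-methylribonucleotide whose 3' backbone linkage is a
phosphorothioate.  Example: ``C(ms)A(ms)G(ms)GU`` is a 5-mer whose first
three nucleotides are 2'-O-methylated with phosphorothioate linkages.

Termini are 5'-OH / 3'-OH (the synthetic sgRNA convention), so the full
oligo composition is the sum of nucleoside compositions plus one linkage
acid (phosphoric acid, or thiophosphoric acid for a phosphorothioate)
per internucleotide bond, losing two waters per bond.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterator, List, Sequence, Tuple

from .chem import (
    Composition,
    METHYLENE,
    PHOSPHORIC_ACID,
    THIOPHOSPHORIC_ACID,
    WATER,
)

BASES = ("A", "C", "G", "U")

#: ribonucleoside compositions (base + ribose, free 5'/3' hydroxyls)
NUCLEOSIDE = {
    "A": Composition.from_dict({"C": 10, "H": 13, "N": 5, "O": 4}),
    "C": Composition.from_dict({"C": 9, "H": 13, "N": 3, "O": 5}),
    "G": Composition.from_dict({"C": 10, "H": 13, "N": 5, "O": 5}),
    "U": Composition.from_dict({"C": 9, "H": 12, "N": 2, "O": 6}),
}


class OligoParseError(ValueError):
    """Sequence syntax error; ``offset`` is the 0-based position in the text."""

    def __init__(self, message: str, offset: int):
        super().__init__(f"{message} (offset {offset})")
        self.offset = offset


@dataclass(frozen=True)
class Nucleotide:
    """One position of a modified RNA: base plus modification flags.

    ``thio_linkage`` refers to the phosphodiester bond on the 3' side of
    this nucleotide.
    """

    base: str
    ribose_methyl: bool = False
    thio_linkage: bool = False

    def __post_init__(self) -> None:
        if self.base not in BASES:
            raise ValueError(f"invalid base {self.base!r}")

    @property
    def nucleoside_composition(self) -> Composition:
        comp = NUCLEOSIDE[self.base]
        if self.ribose_methyl:
            comp = comp + METHYLENE
        return comp

    @property
    def linkage_acid(self) -> Composition:
        return THIOPHOSPHORIC_ACID if self.thio_linkage else PHOSPHORIC_ACID

    def token(self) -> str:
        if self.thio_linkage:
            return f"{self.base}(ms)"
        if self.ribose_methyl:
            return f"{self.base}(m)"
        return self.base


@dataclass(frozen=True)
class OligoSequence:
    """An ordered modified-RNA sequence; position 1 is the 5' end."""

    nucleotides: Tuple[Nucleotide, ...]
    name: str = ""

    def __post_init__(self) -> None:
        if not self.nucleotides:
            raise ValueError("empty oligonucleotide")
        object.__setattr__(self, "nucleotides", tuple(self.nucleotides))

    def __len__(self) -> int:
        return len(self.nucleotides)

    def __iter__(self) -> Iterator[Nucleotide]:
        return iter(self.nucleotides)

    def at(self, position: int) -> Nucleotide:
        """1-based access from the 5' end."""
        if not 1 <= position <= len(self):
            raise IndexError(f"position {position} outside 1..{len(self)}")
        return self.nucleotides[position - 1]

    def subsequence(self, start: int, end: int, name: str = "") -> "OligoSequence":
        """Nucleotides ``start``..``end`` inclusive, 1-based."""
        if not (1 <= start <= end <= len(self)):
            raise IndexError(f"range {start}..{end} outside 1..{len(self)}")
        return OligoSequence(self.nucleotides[start - 1:end], name or self.name)

    def spacer(self, length: int = 20) -> "OligoSequence":
        """The first ``length`` nucleotides from the 5' end."""
        return self.subsequence(1, min(length, len(self)),
                                f"{self.name} spacer" if self.name else "spacer")

    def with_base(self, position: int, base: str) -> "OligoSequence":
        """Copy with the base at ``position`` replaced, modification flags kept."""
        nt = self.at(position)
        nts = list(self.nucleotides)
        nts[position - 1] = Nucleotide(base, nt.ribose_methyl, nt.thio_linkage)
        return OligoSequence(tuple(nts), self.name)

    def format(self) -> str:
        return format_sequence(self)

    def __str__(self) -> str:
        return self.format()


def parse_sequence(text: str, name: str = "") -> OligoSequence:
    """Parse the token syntax into an :class:`OligoSequence`.

    Raises :class:`OligoParseError` with the offending offset for unknown
    characters/modifiers, an empty string, or a trailing ``(ms)`` (the
    phosphorothioate flag needs a 3' neighbour).
    """
    if not text:
        raise OligoParseError("empty sequence", 0)
    nts: List[Nucleotide] = []
    pos = 0
    n = len(text)
    while pos < n:
        base = text[pos]
        if base not in BASES:
            raise OligoParseError(f"unknown nucleotide {base!r}", pos)
        pos += 1
        methyl = thio = False
        if pos < n and text[pos] == "(":
            close = text.find(")", pos)
            if close < 0:
                raise OligoParseError("unterminated modifier", pos)
            modifier = text[pos + 1:close]
            if modifier == "m":
                methyl = True
            elif modifier == "ms":
                # (ms) implies a 2'-O-methylribonucleotide as well
                methyl = thio = True
            else:
                raise OligoParseError(f"unknown modifier {modifier!r}", pos)
            pos = close + 1
        nts.append(Nucleotide(base, methyl, thio))
    if nts[-1].thio_linkage:
        raise OligoParseError(
            "trailing (ms): last nucleotide has no 3' linkage", n - 1
        )
    return OligoSequence(tuple(nts), name)


def format_sequence(oligo: OligoSequence) -> str:
    """Render back to the token syntax (inverse of :func:`parse_sequence`)."""
    return "".join(nt.token() for nt in oligo)


def elemental_composition(oligo: OligoSequence) -> Composition:
    """Neutral elemental composition of a 5'-OH/3'-OH oligonucleotide.

    Sum of nucleoside compositions plus one linkage acid per
    internucleotide bond (thiophosphoric acid where the 5' partner is
    phosphorothioate-flagged), condensing out two waters per bond.
    """
    total = Composition()
    for i, nt in enumerate(oligo):
        total = total + nt.nucleoside_composition
        if i < len(oligo) - 1:
            total = (total + nt.linkage_acid) - (WATER * 2)
    return total


def neutral_mass(comp: Composition, mode: str = "monoisotopic") -> float:
    """Neutral mass in Da; ``mode`` is 'monoisotopic' or 'average'."""
    return comp.mass(mode)


def enumerate_substitutions(
    oligo: OligoSequence,
    region: Tuple[int, int] | None = None,
    exclude_cu: bool = False,
) -> List[Tuple[int, str, str, OligoSequence]]:
    """All single-base substitutions of ``region`` (1-based, inclusive).

    Each entry is ``(position, from_base, to_base, variant_sequence)``;
    the modification scaffold is preserved at every position.  With
    ``exclude_cu`` the C<->U pairs (isotopically overlapping at +-0.984 Da)
    are omitted; they are handled by the dedicated isotope-mixture fit.
    An empty region yields an empty list.
    """
    if region is None:
        region = (1, len(oligo))
    start, end = region
    out: List[Tuple[int, str, str, OligoSequence]] = []
    if start > end:
        return out
    if not (1 <= start and end <= len(oligo)):
        raise IndexError(f"region {start}..{end} outside 1..{len(oligo)}")
    for position in range(start, end + 1):
        from_base = oligo.at(position).base
        for to_base in BASES:
            if to_base == from_base:
                continue
            if exclude_cu and {from_base, to_base} == {"C", "U"}:
                continue
            variant = oligo.with_base(position, to_base)
            variant = OligoSequence(
                variant.nucleotides,
                f"{oligo.name or 'oligo'} {position}{from_base}>{to_base}",
            )
            out.append((position, from_base, to_base, variant))
    return out
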