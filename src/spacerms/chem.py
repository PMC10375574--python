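"""Elemental constants and composition arithmetic.

Masses come in two flavours used throughout the package:

* **monoisotopic** — exact mass of the lightest isotope of each element
  (CODATA/AME values), used for fragment m/z prediction and isotope
  pattern anchoring;
* **average** — standard atomic weights, used for intact-oligo average
  masses as reported on synthesis certificates.  The average table is the
  1995 IUPAC standard-atomic-weights set, which is what the mass
  calculators embedded in common oligonucleotide QC software use; newer
  abridged tables shift a 100-mer by ~0.1 Da.

Natural isotope abundances (IUPAC representative values) back the
isotopologue convolution in :mod:`spacerms.isotopes`.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Iterator, Mapping, Tuple

ELEMENTS: Tuple[str, ...] = ("C", "H", "N", "O", "P", "S")

#: exact mass of the lightest isotope, Da
MONOISOTOPIC_MASS: Dict[str, float] = {
    "C": 12.0,
    "H": 1.00782503207,
    "N": 14.0030740048,
    "O": 15.9949146196,
    "P": 30.97376163,
    "S": 31.97207100,
}

#: standard atomic weights (1995 IUPAC), Da
AVERAGE_MASS: Dict[str, float] = {
    "C": 12.011,
    "H": 1.00794,
    "N": 14.0067,
    "O": 15.9994,
    "P": 30.973762,
    "S": 32.066,
}

#: (isotope exact mass, natural abundance) sorted by mass, per element
ISOTOPES: Dict[str, Tuple[Tuple[float, float], ...]] = {
    "H": ((1.00782503207, 0.999885), (2.0141017778, 0.000115)),
    "C": ((12.0, 0.9893), (13.0033548378, 0.0107)),
    "N": ((14.0030740048, 0.99636), (15.0001088982, 0.00364)),
    "O": ((15.9949146196, 0.99757), (16.9991317, 0.00038), (17.9991610, 0.00205)),
    "P": ((30.97376163, 1.0),),
    "S": (
        (31.97207100, 0.9499),
        (32.97145876, 0.0075),
        (33.96786690, 0.0425),
        (35.96708076, 0.0001),
    ),
}

#: mass of a proton (charge carrier in negative-mode deprotonation), Da
PROTON_MASS = 1.007276466879

#: 13C − 12C mass difference; nominal isotopologue spacing, Da
NEUTRON_SPACING = 1.0033548378


class CompositionError(ValueError):
    """Raised when composition arithmetic would produce negative counts."""


@dataclass(frozen=True)
class Composition:
    """An elemental composition over C/H/N/O/P/S with non-negative counts.

    Supports addition, subtraction (raising :class:`CompositionError` if a
    count would go negative) and integer scaling.  Instances are hashable
    so isotope patterns can be cached per composition.
    """

    counts: Tuple[Tuple[str, int], ...] = field(default=())

    def __post_init__(self) -> None:
        cleaned = []
        for el, n in self.counts:
            if el not in ELEMENTS:
                raise CompositionError(f"unknown element {el!r}")
            if n < 0:
                raise CompositionError(f"negative count for {el}: {n}")
            if n:
                cleaned.append((el, int(n)))
        cleaned.sort()
        object.__setattr__(self, "counts", tuple(cleaned))

    @classmethod
    def from_dict(cls, d: Mapping[str, int]) -> "Composition":
        return cls(tuple(d.items()))

    def as_dict(self) -> Dict[str, int]:
        return dict(self.counts)

    def __getitem__(self, el: str) -> int:
        return dict(self.counts).get(el, 0)

    def __iter__(self) -> Iterator[Tuple[str, int]]:
        return iter(self.counts)

    def __bool__(self) -> bool:
        return bool(self.counts)

    def __add__(self, other: "Composition") -> "Composition":
        d = self.as_dict()
        for el, n in other:
            d[el] = d.get(el, 0) + n
        return Composition.from_dict(d)

    def __sub__(self, other: "Composition") -> "Composition":
        d = self.as_dict()
        for el, n in other:
            d[el] = d.get(el, 0) - n
            if d[el] < 0:
                raise CompositionError(
                    f"subtraction yields negative {el} count ({d[el]})"
                )
        return Composition.from_dict(d)

    def __mul__(self, k: int) -> "Composition":
        if not isinstance(k, int) or k < 0:
            raise CompositionError("composition scaling requires a non-negative int")
        return Composition.from_dict({el: n * k for el, n in self.counts})

    __rmul__ = __mul__

    def mass(self, mode: str = "monoisotopic") -> float:
        """Neutral mass in Da; ``mode`` is 'monoisotopic' or 'average'."""
        if mode == "monoisotopic":
            table = MONOISOTOPIC_MASS
        elif mode == "average":
            table = AVERAGE_MASS
        else:
            raise ValueError(f"unknown mass mode {mode!r}")
        return sum(table[el] * n for el, n in self.counts)

    @property
    def monoisotopic_mass(self) -> float:
        return self.mass("monoisotopic")

    @property
    def average_mass(self) -> float:
        return self.mass("average")

    def formula(self) -> str:
        """Hill-ish formula string in fixed C,H,N,O,P,S order."""
        d = self.as_dict()
        return "".join(
            f"{el}{d[el] if d[el] > 1 else ''}" for el in ELEMENTS if d.get(el)
        )

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return f"Composition({self.formula() or 'empty'})"


# Small building blocks shared by the oligo and fragment models.
WATER = Composition.from_dict({"H": 2, "O": 1})
METHYLENE = Composition.from_dict({"C": 1, "H": 2})
PHOSPHORIC_ACID = Composition.from_dict({"H": 3, "P": 1, "O": 4})
THIOPHOSPHORIC_ACID = Composition.from_dict({"H": 3, "P": 1, "O": 3, "S": 1})
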