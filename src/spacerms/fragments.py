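"""c/y backbone fragment species and negative-mode m/z arithmetic.

Collision-activated dissociation of RNA cleaves the P-O5' bond; the
5'-terminal product retaining the cleavage-site (thio)phosphate is the
c-ion, the 3'-terminal product with a free 5'-OH is the y-ion.  For an
N-mer, composition(c_n) + composition(y_{N-n}) equals the parent
composition exactly.

Ions are detected deprotonated: m/z = (M - z*m_p) / z for the z- ion.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence, Tuple

import pandas as pd

from .chem import Composition, PROTON_MASS, WATER
from .oligo import Nucleotide, OligoSequence

ION_TYPES = ("c", "y")


@dataclass(frozen=True)
class FragmentSpecies:
    """A neutral c- or y-fragment of a parent oligonucleotide."""

    parent_name: str
    ion_type: str
    index: int
    composition: Composition

    @property
    def neutral_mono_mass(self) -> float:
        return self.composition.monoisotopic_mass

    def mz(self, z: int) -> float:
        return ion_mz(self.neutral_mono_mass, z)

    def label(self) -> str:
        return f"{self.ion_type}{self.index}"


def ion_mz(neutral_mass: float, z: int) -> float:
    """m/z of the z- deprotonated ion of a neutral of mass M."""
    if z < 1:
        raise ValueError(f"charge must be >= 1, got {z}")
    return (neutral_mass - z * PROTON_MASS) / z


def c_prefix_composition(nucleotides: Sequence[Nucleotide]) -> Composition:
    """c-type composition of a 5' prefix: n nucleosides + n linkage acids
    (the internal n-1 plus the cleavage-site acid of the last nucleotide)
    minus 2n waters.  Also used by the de novo search on partial sequences.
    """
    total = Composition()
    for nt in nucleotides:
        total = (total + nt.nucleoside_composition + nt.linkage_acid) - (WATER * 2)
    return total


def c_fragment(oligo: OligoSequence, n: int) -> FragmentSpecies:
    """The c_n fragment (first n nucleotides plus the cleavage-site
    phosphate/thiophosphate); valid for 1 <= n <= len-1."""
    _check_index(oligo, n)
    comp = c_prefix_composition(oligo.nucleotides[:n])
    return FragmentSpecies(oligo.name, "c", n, comp)


def y_fragment(oligo: OligoSequence, n: int) -> FragmentSpecies:
    """The y_n fragment (last n nucleotides, free 5'-OH); the n-1 internal
    linkages keep their (thio)phosphates."""
    _check_index(oligo, n)
    nts = oligo.nucleotides[len(oligo) - n:]
    total = Composition()
    for i, nt in enumerate(nts):
        total = total + nt.nucleoside_composition
        if i < len(nts) - 1:
            total = (total + nt.linkage_acid) - (WATER * 2)
    return FragmentSpecies(oligo.name, "y", n, total)


def fragment(oligo: OligoSequence, ion_type: str, n: int) -> FragmentSpecies:
    if ion_type == "c":
        return c_fragment(oligo, n)
    if ion_type == "y":
        return y_fragment(oligo, n)
    raise ValueError(f"unsupported ion type {ion_type!r}; expected c or y")


def _check_index(oligo: OligoSequence, n: int) -> None:
    if not 1 <= n <= len(oligo) - 1:
        raise ValueError(
            f"fragment index {n} outside 1..{len(oligo) - 1} for {len(oligo)}-mer"
        )


def fragment_table(
    oligo: OligoSequence,
    ion_types: Iterable[str] = ("c",),
    indices: Iterable[int] | None = None,
    charges: Iterable[int] = (1, 2, 3, 4, 5, 6, 7),
) -> pd.DataFrame:
    """Theoretical fragment m/z table (one row per ion/index/charge),
    exportable as TSV."""
    idx: Tuple[int, ...] = tuple(indices) if indices is not None else tuple(
        range(1, len(oligo))
    )
    rows = []
    for ion_type in ion_types:
        for n in idx:
            frag = fragment(oligo, ion_type, n)
            for z in charges:
                rows.append(
                    {
                        "ion_type": ion_type,
                        "index": n,
                        "charge": z,
                        "mz": frag.mz(z),
                        "neutral_mono_mass": frag.neutral_mono_mass,
                        "composition": frag.composition.formula(),
                    }
                )
    return pd.DataFrame(rows)
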