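"""Bundled reference guide-RNA sequences.

A 100-mer Cas9 single-guide RNA ("gRNA X"), four variants carrying one
spacer base substitution each (XA: 2 A>U, XB: 11 G>A, XC: 20 U>G,
XD: 5 U>C), and a guide with a highly dissimilar spacer ("gRNA Y").
The spacer is the first 20 nucleotides; the tracr scaffold (21..100) is
heavily 2'-O-methylated and near-identical across guides.  These serve
as the standard inputs for the validation and simulation studies
throughout the package.
"""

from __future__ import annotations

from typing import Dict

from .oligo import OligoSequence, parse_sequence

_TRACR_X = (
    "G(m)UUUUAGA(m)G(m)C(m)U(m)A(m)G(m)A(m)A(m)A(m)U(m)A(m)G(m)C(m)A(m)A(m)"
    "GUUA(m)AA(m)AU(m)AA(m)G(m)G(m)C(m)U(m)A(m)GUC(m)C(m)GUUAU(m)C(m)AAC(m)"
    "U(m)U(m)G(m)A(m)A(m)A(m)A(m)A(m)G(m)U(m)G(m)GC(m)A(m)C(m)C(m)G(m)A(m)"
    "G(m)U(m)C(m)G(m)G(m)U(m)G(m)C(m)U(ms)U(ms)U(ms)U(m)"
)
# gRNA Y's tracr differs from X's at three methylation sites
_TRACR_Y = (
    "G(m)UUUUAGA(m)G(m)C(m)U(m)A(m)GA(m)A(m)A(m)U(m)A(m)G(m)C(m)A(m)A(m)"
    "GUUA(m)AA(m)AU(m)AA(m)G(m)G(m)C(m)U(m)A(m)GUC(m)C(m)GUUAU(m)C(m)AAC(m)"
    "U(m)U(m)GA(m)A(m)A(m)A(m)A(m)G(m)U(m)G(m)GC(m)A(m)C(m)C(m)G(m)A(m)"
    "G(m)U(m)C(m)G(m)G(m)U(m)G(m)C(m)U(ms)U(ms)U(ms)U(m)"
)

SEQUENCE_TEXTS: Dict[str, str] = {
    "gRNA X": "C(ms)A(ms)G(ms)GUUCCAUGGGAUGCUCU" + _TRACR_X,
    "gRNA XA": "C(ms)U(ms)G(ms)GUUCCAUGGGAUGCUCU" + _TRACR_X,
    "gRNA XB": "C(ms)A(ms)G(ms)GUUCCAUAGGAUGCUCU" + _TRACR_X,
    "gRNA XC": "C(ms)A(ms)G(ms)GUUCCAUGGGAUGCUCG" + _TRACR_X,
    "gRNA XD": "C(ms)A(ms)G(ms)GCUCCAUGGGAUGCUCU" + _TRACR_X,
    "gRNA Y": "C(ms)C(ms)C(ms)GCUCGUUAACGCAACGG" + _TRACR_Y,
}


def reference_sequence(name: str) -> OligoSequence:
    """One of the bundled guides by name ('gRNA X', 'gRNA XA', ...)."""
    try:
        text = SEQUENCE_TEXTS[name]
    except KeyError:
        raise KeyError(
            f"unknown reference sequence {name!r}; "
            f"available: {', '.join(SEQUENCE_TEXTS)}"
        ) from None
    return parse_sequence(text, name=name)


def all_references() -> Dict[str, OligoSequence]:
    return {name: reference_sequence(name) for name in SEQUENCE_TEXTS}
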