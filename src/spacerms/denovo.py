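"""De novo reconstruction of spacer sequences and modification placements
from c-ion ladders.

The spacer search starts from a scaffold of "empty" nucleotides that
carries only the per-position modification flags.  Partial sequences are
extended 5'-to-3': at position k each survivor is extended by A, G, C
and U, and an extension survives only if a c_k fragment of the extended
prefix matches the spectrum.  Because the C and U forms differ by just
0.984 Da (the 13C peak of the C form sits 0.019 Da from the U
monoisotopic), a C or U call is verified by an isotopic mixture fit; if
both forms carry at least 5 % of the envelope the search branches into
both sequences.  At checkpoint lengths (5, 10, 15, 20) candidates are
scored and each set of isomeric (equal-mass) prefixes is reduced to its
best scorer, suppressing sequence scrambles.

Scores: the raw score is the summed intensity of all matched fragments
weighted by their squared cosine; the coverage-weighted score further
multiplies by the squared fraction of positions with fragment evidence.

The impurity-tag variant relaxes the full-ladder requirement: one
missed fragment is allowed per five nucleotides (never within the first
three positions, whose fragments are the most abundant).

The modification variant inverts the unknowns: bases are known and the
search assigns 2'-O-methyl / phosphorothioate flags per position, out
to position 28, requiring complete c-coverage over the spacer and
allowing at most two missed cleavages beyond it.  When a flanking
fragment is missing, equal-evidence placements are merged and reported
as a sequence stretch.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .chem import Composition
from .fragments import FragmentSpecies, c_prefix_composition
from .impurity import extract_envelope, fit_cu_mixture
from .matching import (
    DEFAULT_MIN_COSINE,
    DEFAULT_TOL,
    SPACER_CHARGES,
    FragmentMatch,
    match_fragment,
)
from .isotopes import isotope_distribution
from .oligo import BASES, Nucleotide, OligoSequence, format_sequence
from .spectra import Spectrum

CHECKPOINTS = (5, 10, 15, 20)
#: minimum envelope share for a C/U form to spawn its branch
CU_BRANCH_THRESHOLD = 0.05
DEFAULT_BEAM = 512


@dataclass(frozen=True)
class Scaffold:
    """Per-position modification flags with unknown bases.

    ``thio`` refers to the 3' linkage of each position, as in
    :class:`~spacerms.oligo.Nucleotide`.
    """

    methyl: Tuple[bool, ...]
    thio: Tuple[bool, ...]

    def __post_init__(self) -> None:
        if len(self.methyl) != len(self.thio):
            raise ValueError("flag vectors must have equal length")

    def __len__(self) -> int:
        return len(self.methyl)

    @classmethod
    def from_oligo(cls, oligo: OligoSequence, length: int | None = None) -> "Scaffold":
        n = length or min(20, len(oligo))
        nts = oligo.nucleotides[:n]
        return cls(
            tuple(nt.ribose_methyl for nt in nts),
            tuple(nt.thio_linkage for nt in nts),
        )

    def nucleotide(self, position: int, base: str) -> Nucleotide:
        return Nucleotide(base, self.methyl[position - 1], self.thio[position - 1])


@dataclass(frozen=True)
class DenovoCandidate:
    """A (partial) sequence call with its scores and coverage."""

    nucleotides: Tuple[Nucleotide, ...]
    score: float              # sum of abundance * cosine^2 over matches
    coverage: float           # matched positions / sequence length
    missed: Tuple[int, ...]   # positions with no fragment evidence

    @property
    def weighted_score(self) -> float:
        return self.score * self.coverage**2

    @property
    def sequence(self) -> str:
        return format_sequence(OligoSequence(self.nucleotides))

    @property
    def bases(self) -> str:
        return "".join(nt.base for nt in self.nucleotides)


@dataclass(frozen=True)
class _Partial:
    nts: Tuple[Nucleotide, ...]
    score: float
    missed: Tuple[int, ...]

    def mass_key(self) -> float:
        return round(c_prefix_composition(self.nts).monoisotopic_mass, 3)


def _match_prefix(
    spectrum: Spectrum,
    nts: Tuple[Nucleotide, ...],
    charges: Tuple[int, ...],
    tol: float,
    min_cosine: float,
) -> List[FragmentMatch]:
    comp = c_prefix_composition(nts)
    frag = FragmentSpecies("denovo", "c", len(nts), comp)
    found = []
    for z in charges:
        m = match_fragment(spectrum, frag, z, tol=tol, min_cosine=min_cosine)
        if m is not None:
            found.append(m)
    return found


def _cu_fractions(
    spectrum: Spectrum,
    c_nts: Tuple[Nucleotide, ...],
    u_nts: Tuple[Nucleotide, ...],
    matches_c: List[FragmentMatch],
    matches_u: List[FragmentMatch],
    tol: float,
) -> Optional[float]:
    """Fraction of the U form in the observed envelope at the best-matched
    charge; None if no usable envelope."""
    best = max(matches_c + matches_u, key=lambda m: m.cosine, default=None)
    if best is None:
        return None
    z = best.charge
    comp_c = c_prefix_composition(c_nts)
    comp_u = c_prefix_composition(u_nts)
    pat_c = isotope_distribution(comp_c, z)
    pat_u = isotope_distribution(comp_u, z)
    obs = extract_envelope(
        spectrum, np.concatenate([pat_c.mz, pat_u.mz]), z, tol
    )
    if obs is None:
        return None
    try:
        fit = fit_cu_mixture(obs, comp_c, comp_u)
    except ValueError:
        return None
    return fit.fraction_substitute


def _reduce_isomeric(cands: List[_Partial], length: int) -> List[_Partial]:
    """Keep the best coverage-weighted scorer per equal-mass prefix set."""
    best: Dict[float, _Partial] = {}
    for cand in cands:
        key = cand.mass_key()
        weighted = cand.score * ((length - len(cand.missed)) / length) ** 2
        prev = best.get(key)
        if prev is None:
            best[key] = cand
            continue
        prev_weighted = prev.score * ((length - len(prev.missed)) / length) ** 2
        cand_bases = tuple(nt.base for nt in cand.nts)
        prev_bases = tuple(nt.base for nt in prev.nts)
        if weighted > prev_weighted or (
            weighted == prev_weighted
            and cand_bases < prev_bases  # lexicographic tie-break, documented
        ):
            best[key] = cand
    return list(best.values())


def _search_bases(
    spectrum: Spectrum,
    scaffold: Scaffold,
    length: int,
    miss_budget: int,
    charges: Tuple[int, ...],
    tol: float,
    min_cosine: float,
    beam: int,
    cu_threshold: float,
) -> List[DenovoCandidate]:
    survivors: List[_Partial] = [_Partial((), 0.0, ())]
    for k in range(1, length + 1):
        nxt: List[_Partial] = []
        for cand in survivors:
            ext = {
                base: cand.nts + (scaffold.nucleotide(k, base),) for base in BASES
            }
            matches = {
                base: _match_prefix(spectrum, ext[base], charges, tol, min_cosine)
                for base in BASES
            }
            accept = {base: bool(matches[base]) for base in BASES}
            if accept["C"] or accept["U"]:
                f_u = _cu_fractions(
                    spectrum, ext["C"], ext["U"], matches["C"], matches["U"], tol
                )
                if f_u is not None:
                    accept["C"] = accept["C"] and (1.0 - f_u) >= cu_threshold
                    accept["U"] = accept["U"] and f_u >= cu_threshold
                    if not (accept["C"] or accept["U"]):
                        # fit contradicted both raw calls; fall back to them
                        accept["C"] = bool(matches["C"])
                        accept["U"] = bool(matches["U"])
            extended = False
            for base in BASES:
                if accept[base]:
                    gain = sum(m.abundance * m.cosine**2 for m in matches[base])
                    nxt.append(_Partial(ext[base], cand.score + gain, cand.missed))
                    extended = True
            if not extended and len(cand.missed) < miss_budget and k > 3:
                for base in BASES:
                    nxt.append(
                        _Partial(ext[base], cand.score, cand.missed + (k,))
                    )
        survivors = nxt
        if not survivors:
            return []
        if k in CHECKPOINTS or k == length:
            survivors = _reduce_isomeric(survivors, k)
        if len(survivors) > beam:
            survivors.sort(
                key=lambda c: -c.score * ((k - len(c.missed)) / k) ** 2
            )
            survivors = survivors[:beam]
    out = [
        DenovoCandidate(
            c.nts, c.score, (length - len(c.missed)) / length, c.missed
        )
        for c in survivors
    ]
    out.sort(key=lambda c: (-c.weighted_score, c.bases))
    return out


def denovo_spacer(
    spectrum: Spectrum,
    scaffold: Scaffold,
    max_len: int = 20,
    charges: Iterable[int] = SPACER_CHARGES,
    tol: float = DEFAULT_TOL,
    min_cosine: float = DEFAULT_MIN_COSINE,
    beam: int = DEFAULT_BEAM,
    cu_threshold: float = CU_BRANCH_THRESHOLD,
) -> List[DenovoCandidate]:
    """Full-coverage de novo spacer read-out (every c_1..c_k must match).

    Returns candidates ranked by coverage-weighted score; empty when no
    c_1 matches any base.
    """
    length = min(max_len, len(scaffold))
    return _search_bases(
        spectrum, scaffold, length, 0, tuple(charges), tol, min_cosine,
        beam, cu_threshold,
    )


def denovo_impurity_tags(
    spectrum: Spectrum,
    scaffold: Scaffold,
    tag_len: int,
    missed_per_5: int = 1,
    charges: Iterable[int] = SPACER_CHARGES,
    tol: float = DEFAULT_TOL,
    min_cosine: float = DEFAULT_MIN_COSINE,
    beam: int = DEFAULT_BEAM,
    cu_threshold: float = CU_BRANCH_THRESHOLD,
) -> List[DenovoCandidate]:
    """Low-abundance impurity tag search with a missed-fragment budget of
    ``missed_per_5`` per five nucleotides (misses only after c_3)."""
    if tag_len not in (5, 10, 15, 20):
        raise ValueError("tag_len must be one of 5, 10, 15, 20")
    budget = (tag_len // 5) * missed_per_5
    return _search_bases(
        spectrum, scaffold, tag_len, budget, tuple(charges), tol, min_cosine,
        beam, cu_threshold,
    )


# --- modification placement ------------------------------------------------

#: allowed per-position (methyl, thio) states; phosphorothioate implies
#: the 2'-O-methyl on the same nucleotide in this chemistry vocabulary
FLAG_STATES = ((False, False), (True, False), (True, True))


@dataclass(frozen=True)
class ModificationAssignment:
    """One ranked flag placement over positions 1..max_pos."""

    methyl_positions: frozenset
    thio_positions: frozenset
    score: float
    coverage: float
    missed: Tuple[int, ...]

    @property
    def weighted_score(self) -> float:
        return self.score * self.coverage**2


@dataclass(frozen=True)
class _FlagPartial:
    flags: Tuple[Tuple[bool, bool], ...]
    score: float
    missed: Tuple[int, ...]


def denovo_modifications(
    spectrum: Spectrum,
    base_sequence: str,
    max_pos: int = 28,
    max_missed: int = 2,
    charges: Iterable[int] = tuple(range(1, 13)),
    tol: float = DEFAULT_TOL,
    min_cosine: float = DEFAULT_MIN_COSINE,
    beam: int = DEFAULT_BEAM,
) -> List[ModificationAssignment]:
    """Assign 2'-O-methyl and phosphorothioate sites on a known base
    sequence via c-ion matching out to ``max_pos``.

    Complete c-coverage is required over positions 1..20; up to
    ``max_missed`` missed cleavages are tolerated from 21 to ``max_pos``.
    Equal-evidence placements (e.g. a methyl on either side of a missed
    cleavage) are returned as separate, equally scored assignments;
    :func:`summarize_placements` merges them into stretches.
    """
    bases = [b for b in base_sequence if not b.isspace()]
    for b in bases:
        if b not in BASES:
            raise ValueError(f"invalid base {b!r} in base sequence")
    length = min(max_pos, len(bases))
    charges = tuple(charges)
    survivors: List[_FlagPartial] = [_FlagPartial((), 0.0, ())]
    for k in range(1, length + 1):
        nxt: List[_FlagPartial] = []
        for cand in survivors:
            for methyl, thio in FLAG_STATES:
                flags = cand.flags + ((methyl, thio),)
                nts = tuple(
                    Nucleotide(bases[i], fl[0], fl[1])
                    for i, fl in enumerate(flags)
                )
                matches = _match_prefix(spectrum, nts, charges, tol, min_cosine)
                if matches:
                    gain = sum(m.abundance * m.cosine**2 for m in matches)
                    nxt.append(_FlagPartial(flags, cand.score + gain, cand.missed))
                elif k > 20 and len(cand.missed) < max_missed:
                    nxt.append(_FlagPartial(flags, cand.score, cand.missed + (k,)))
        survivors = nxt
        if not survivors:
            return []
        if len(survivors) > beam:
            survivors.sort(key=lambda c: -c.score)
            survivors = survivors[:beam]
    out = []
    for cand in survivors:
        methyl = frozenset(
            i + 1 for i, (m, _) in enumerate(cand.flags) if m
        )
        thio = frozenset(
            i + 1 for i, (_, t) in enumerate(cand.flags) if t
        )
        out.append(
            ModificationAssignment(
                methyl, thio, cand.score,
                (length - len(cand.missed)) / length, cand.missed,
            )
        )
    out.sort(key=lambda a: (-a.weighted_score, sorted(a.methyl_positions)))
    return out


def summarize_placements(
    assignments: Sequence[ModificationAssignment],
    rel_tol: float = 1e-6,
) -> Dict[str, object]:
    """Merge the top equal-score assignment group into certain positions
    and ambiguous stretches.

    A modification present in every member of the group is *certain*;
    positions on which members disagree are reported as sorted ambiguous
    stretches (the interval semantics used when a flanking fragment is
    missing).
    """
    if not assignments:
        return {"methyl": set(), "methyl_stretches": [], "thio": set(),
                "thio_stretches": [], "missed": ()}
    top = assignments[0].weighted_score
    group = [
        a for a in assignments
        if abs(a.weighted_score - top) <= rel_tol * max(top, 1.0)
    ]
    methyl_certain = frozenset.intersection(*[a.methyl_positions for a in group])
    methyl_union = frozenset.union(*[a.methyl_positions for a in group])
    thio_certain = frozenset.intersection(*[a.thio_positions for a in group])
    thio_union = frozenset.union(*[a.thio_positions for a in group])

    def stretches(union, certain):
        amb = sorted(union - certain)
        out = []
        for p in amb:
            if out and p == out[-1][-1] + 1:
                out[-1].append(p)
            else:
                out.append([p])
        return [tuple(s) for s in out]

    return {
        "methyl": set(methyl_certain),
        "methyl_stretches": stretches(methyl_union, methyl_certain),
        "thio": set(thio_certain),
        "thio_stretches": stretches(thio_union, thio_certain),
        "missed": assignments[0].missed,
    }


def candidates_frame(cands: Sequence[DenovoCandidate]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "rank": i + 1,
                "sequence": c.sequence,
                "score": c.score,
                "weighted_score": c.weighted_score,
                "coverage": c.coverage,
                "missed": len(c.missed),
            }
            for i, c in enumerate(cands)
        ]
    )
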