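"""Fragment-to-spectrum assignment with isotopic-fidelity scoring.

A theoretical fragment is accepted when (i) each isotopologue finds a
peak within the mass tolerance (default 0.01 m/z), (ii) at least two
*adjacent* isotopologues are matched, and (iii) the cosine similarity
between the observed and theoretical abundance vectors exceeds the
cutoff (default 0.80).  Fragment abundance is the observed intensity at
the most abundant theoretical isotopologue.

False-discovery rates are estimated with mass-shifted decoys: the
theoretical fragment list is offset by every nonzero multiple of 50 ppm
within +-1000 ppm (40 offsets); hits on offset lists are random hits and
FDR = mean(random hits) / target hits.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Sequence, Tuple

import numpy as np
import pandas as pd

from .fragments import FragmentSpecies, fragment
from .isotopes import IsotopePattern, isotope_distribution
from .oligo import OligoSequence
from .spectra import Spectrum

DEFAULT_TOL = 0.01
DEFAULT_MIN_COSINE = 0.80
DEFAULT_MIN_CONSECUTIVE = 2
SPACER_CHARGES: Tuple[int, ...] = (1, 2, 3, 4, 5, 6, 7)
FULL_CHARGES: Tuple[int, ...] = tuple(range(1, 26))


def cosine_score(theoretical: np.ndarray, observed: np.ndarray) -> float:
    """Cosine similarity of two aligned abundance vectors; 0 if either is
    all-zero.  Scale-invariant."""
    theoretical = np.asarray(theoretical, dtype=float)
    observed = np.asarray(observed, dtype=float)
    if theoretical.shape != observed.shape:
        raise ValueError("vectors must be aligned to the same length")
    denom = np.linalg.norm(theoretical) * np.linalg.norm(observed)
    if denom == 0:
        return 0.0
    return float(np.dot(theoretical, observed) / denom)


@dataclass(frozen=True)
class FragmentMatch:
    """An accepted fragment-spectrum assignment."""

    fragment: FragmentSpecies
    charge: int
    peak_indices: Tuple[int, ...]     # spectrum index per isotopologue, -1 if unmatched
    mass_error: float                 # m/z units, at the most intense matched isotopologue
    cosine: float
    abundance: float                  # observed counts at the base theoretical peak

    @property
    def n_matched(self) -> int:
        return sum(1 for i in self.peak_indices if i >= 0)


def _nearest_peak(spectrum: Spectrum, mz: float, tol: float) -> int:
    """Index of the nearest peak within tol, ties broken toward higher
    intensity; -1 if none."""
    arr = spectrum.mz
    if arr.size == 0:
        return -1
    i = int(np.searchsorted(arr, mz))
    best = -1
    best_d = tol
    for j in (i - 1, i, i + 1):
        if 0 <= j < arr.size:
            d = abs(arr[j] - mz)
            if d < best_d - 1e-12:
                best, best_d = j, d
            elif best >= 0 and abs(d - best_d) <= 1e-12:
                if spectrum.intensity[j] > spectrum.intensity[best]:
                    best = j
    return best


def _max_consecutive(flags: Sequence[bool]) -> int:
    run = best = 0
    for f in flags:
        run = run + 1 if f else 0
        best = max(best, run)
    return best


def match_pattern(
    spectrum: Spectrum,
    pattern: IsotopePattern,
    tol: float = DEFAULT_TOL,
) -> Tuple[Tuple[int, ...], np.ndarray]:
    """Align each theoretical isotopologue to its nearest spectrum peak.

    Returns (peak indices, observed intensity vector); unmatched
    positions get index -1 and intensity 0.
    """
    indices = []
    observed = np.zeros(len(pattern))
    for k, mz in enumerate(pattern.mz):
        j = _nearest_peak(spectrum, mz, tol)
        indices.append(j)
        if j >= 0:
            observed[k] = spectrum.intensity[j]
    return tuple(indices), observed


def match_fragment(
    spectrum: Spectrum,
    frag: FragmentSpecies,
    z: int,
    tol: float = DEFAULT_TOL,
    min_consecutive: int = DEFAULT_MIN_CONSECUTIVE,
    min_cosine: float = DEFAULT_MIN_COSINE,
    mz_offset_ppm: float = 0.0,
) -> FragmentMatch | None:
    """Attempt to assign ``frag`` at charge ``z``; None when the
    consecutive-isotope or cosine requirement fails.

    ``mz_offset_ppm`` shifts the theoretical m/z values (decoy searches).
    """
    pattern = isotope_distribution(frag.composition, z)
    if mz_offset_ppm:
        pattern = IsotopePattern(
            z, pattern.mz * (1.0 + mz_offset_ppm * 1e-6), pattern.abundance
        )
    indices, observed = match_pattern(spectrum, pattern, tol)
    matched = [i >= 0 for i in indices]
    if _max_consecutive(matched) < min_consecutive:
        return None
    cos = cosine_score(pattern.abundance, observed)
    if cos <= min_cosine:
        return None
    base = pattern.base_peak_index
    abundance = float(observed[base])
    # mass error at the most intense matched isotopologue
    matched_idx = [k for k, ok in enumerate(matched) if ok]
    top = max(matched_idx, key=lambda k: observed[k])
    mass_error = float(spectrum.mz[indices[top]] - pattern.mz[top])
    return FragmentMatch(frag, z, indices, mass_error, cos, abundance)


@dataclass
class CoverageReport:
    """Per-position fragment evidence over a requested index range."""

    oligo_name: str
    oligo_length: int
    index_range: Tuple[int, int]
    matches: Dict[str, Dict[int, List[FragmentMatch]]]

    def covered_sites(self) -> set:
        """Backbone cleavage sites with evidence from any requested ion
        series: c_n covers site n, y_n covers site N - n."""
        sites = set()
        for ion_type, by_index in self.matches.items():
            for n in by_index:
                sites.add(n if ion_type == "c" else self.oligo_length - n)
        return sites

    @property
    def percent(self) -> float:
        lo, hi = self.index_range
        n_sites = hi - lo + 1
        if n_sites <= 0:
            return 0.0
        covered = {s for s in self.covered_sites() if lo <= s <= hi}
        return 100.0 * len(covered) / n_sites

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for ion_type, by_index in self.matches.items():
            for n, ms in sorted(by_index.items()):
                for m in ms:
                    rows.append(
                        {
                            "ion_type": ion_type,
                            "index": n,
                            "charge": m.charge,
                            "mz_error": m.mass_error,
                            "cosine": m.cosine,
                            "abundance": m.abundance,
                        }
                    )
        return pd.DataFrame(
            rows,
            columns=["ion_type", "index", "charge", "mz_error", "cosine", "abundance"],
        )


def sequence_coverage(
    spectrum: Spectrum,
    oligo: OligoSequence,
    ion_types: Iterable[str] = ("c",),
    charges: Iterable[int] = SPACER_CHARGES,
    index_range: Tuple[int, int] | None = None,
    tol: float = DEFAULT_TOL,
    min_cosine: float = DEFAULT_MIN_COSINE,
    min_consecutive: int = DEFAULT_MIN_CONSECUTIVE,
) -> CoverageReport:
    """Match the requested fragment grid and report per-site coverage.

    Spacer mode is c_1..c_20 at 1-..7-; full-sequence mode passes
    ion_types ("c", "y"), charges 1..25 and the full index range.
    """
    if index_range is None:
        index_range = (1, min(20, len(oligo) - 1))
    lo, hi = index_range
    hi = min(hi, len(oligo) - 1)
    matches: Dict[str, Dict[int, List[FragmentMatch]]] = {}
    for ion_type in ion_types:
        by_index: Dict[int, List[FragmentMatch]] = {}
        for n in range(lo, hi + 1):
            frag = fragment(oligo, ion_type, n)
            found = []
            for z in charges:
                m = match_fragment(
                    spectrum, frag, z, tol=tol,
                    min_consecutive=min_consecutive, min_cosine=min_cosine,
                )
                if m is not None:
                    found.append(m)
            if found:
                by_index[n] = found
        matches[ion_type] = by_index
    return CoverageReport(oligo.name, len(oligo), (lo, hi), matches)


def spacer_coverage(spectrum: Spectrum, oligo: OligoSequence, **kwargs) -> CoverageReport:
    """Coverage of the 20-nt spacer by c-ions at 1-..7-."""
    kwargs.setdefault("charges", SPACER_CHARGES)
    return sequence_coverage(spectrum, oligo, ion_types=("c",), **kwargs)


@dataclass
class FdrSummary:
    """Decoy (mass-offset) FDR estimate for one fragment search."""

    fdr: float                      # NaN when undefined (zero target hits)
    target_hits: int
    random_hits: Dict[float, int]   # ppm offset -> hit count
    target_cosines: List[float]
    random_cosines: List[float]

    @property
    def defined(self) -> bool:
        return self.target_hits > 0

    @property
    def mean_random_hits(self) -> float:
        if not self.random_hits:
            return 0.0
        return float(np.mean(list(self.random_hits.values())))


def estimate_fdr(
    spectrum: Spectrum,
    oligo: OligoSequence,
    ion_types: Iterable[str] = ("c",),
    charges: Iterable[int] = SPACER_CHARGES,
    index_range: Tuple[int, int] | None = None,
    offset_max: float = 1000.0,
    step: float = 50.0,
    tol: float = DEFAULT_TOL,
    min_cosine: float = DEFAULT_MIN_COSINE,
    min_consecutive: int = DEFAULT_MIN_CONSECUTIVE,
) -> FdrSummary:
    """Offset-decoy FDR over the requested fragment grid."""
    if index_range is None:
        index_range = (1, min(20, len(oligo) - 1))
    lo, hi = index_range
    hi = min(hi, len(oligo) - 1)
    frags = [
        fragment(oligo, ion_type, n)
        for ion_type in ion_types
        for n in range(lo, hi + 1)
    ]
    charges = tuple(charges)

    def count_hits(offset: float) -> Tuple[int, List[float]]:
        hits = 0
        cosines = []
        for frag in frags:
            for z in charges:
                m = match_fragment(
                    spectrum, frag, z, tol=tol,
                    min_consecutive=min_consecutive, min_cosine=min_cosine,
                    mz_offset_ppm=offset,
                )
                if m is not None:
                    hits += 1
                    cosines.append(m.cosine)
        return hits, cosines

    target_hits, target_cos = count_hits(0.0)
    nsteps = int(round(offset_max / step))
    offsets = [k * step for k in range(-nsteps, nsteps + 1) if k != 0]
    random_hits: Dict[float, int] = {}
    random_cos: List[float] = []
    for off in offsets:
        hits, cosines = count_hits(off)
        random_hits[off] = hits
        random_cos.extend(cosines)
    if target_hits == 0:
        fdr = float("nan")
    else:
        fdr = float(np.mean(list(random_hits.values())) / target_hits)
    return FdrSummary(fdr, target_hits, random_hits, target_cos, random_cos)
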