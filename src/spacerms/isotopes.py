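"""Isotopologue distributions by per-element convolution.

Isotopologues are aggregated by nucleon count (unit-mass binning): all
combinations with the same number of extra neutrons fall in one peak
whose m/z is the abundance-weighted mean of its members.  At QTOF
resolution and a 0.01 m/z matching tolerance, fine structure within a
bin is not resolvable, so this aggregation is exact for our purposes.

The per-element single-atom distributions are convolved with binary
exponentiation, carrying both the probability vector and its first mass
moment so that bin centroids stay exact.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import lru_cache
from typing import Tuple

import numpy as np

from .chem import Composition, ISOTOPES, MONOISOTOPIC_MASS
from .fragments import ion_mz

#: default pruning threshold, relative to the most abundant isotopologue
PRUNE_THRESHOLD = 1e-4


@dataclass(frozen=True)
class IsotopePattern:
    """Peak list of one isotopic envelope at a given charge state.

    ``mz`` is strictly increasing; ``abundance`` is normalized so the most
    abundant peak equals 1.  ``origin`` records whether the pattern is a
    theoretical prediction or was extracted from a spectrum.
    """

    charge: int
    mz: np.ndarray
    abundance: np.ndarray
    origin: str = "theoretical"

    def __post_init__(self) -> None:
        mz = np.asarray(self.mz, dtype=float)
        ab = np.asarray(self.abundance, dtype=float)
        if mz.shape != ab.shape:
            raise ValueError("mz and abundance must be the same length")
        if mz.size > 1 and not np.all(np.diff(mz) > 0):
            raise ValueError("pattern m/z must be strictly increasing")
        object.__setattr__(self, "mz", mz)
        object.__setattr__(self, "abundance", ab)

    def __len__(self) -> int:
        return int(self.mz.size)

    @property
    def base_peak_index(self) -> int:
        return int(np.argmax(self.abundance))


def _conv(a, b):
    """Convolve (probability, mass-moment) pairs."""
    pa, ma = a
    pb, mb = b
    p = np.convolve(pa, pb)
    m = np.convolve(ma, pb) + np.convolve(pa, mb)
    return p, m


@lru_cache(maxsize=4096)
def _aggregate(counts: Tuple[Tuple[str, int], ...]):
    """Neutron-binned isotopologue (probabilities, mean masses) for a
    composition given as sorted (element, count) tuples.  Probabilities
    sum to 1 before any pruning."""
    total = (np.array([1.0]), np.array([0.0]))
    for el, n in counts:
        isos = ISOTOPES[el]
        base = round(isos[0][0])
        size = round(isos[-1][0]) - base + 1
        p = np.zeros(size)
        m = np.zeros(size)
        for mass, ab in isos:
            k = round(mass) - base
            p[k] += ab
            m[k] += ab * mass
        atom = (p, m)
        # binary exponentiation over the atom count
        power = None
        while n:
            if n & 1:
                power = atom if power is None else _conv(power, atom)
            n >>= 1
            if n:
                atom = _conv(atom, atom)
        total = _conv(total, power)
    p, m = total
    keep = p > 0
    masses = np.zeros_like(p)
    masses[keep] = m[keep] / p[keep]
    return p, masses


def aggregate_isotopologues(comp: Composition):
    """(probabilities, neutral masses) per nucleon bin, unpruned;
    probabilities sum to 1.  Exposed for oracle tests."""
    if not comp:
        raise ValueError("empty composition has no isotope distribution")
    return _aggregate(comp.counts)


def isotope_distribution(
    comp: Composition, z: int, prune: float = PRUNE_THRESHOLD
) -> IsotopePattern:
    """Theoretical isotope pattern of the z- deprotonated ion of ``comp``.

    Peaks below ``prune`` of the maximum are dropped; abundances are
    max-normalized.
    """
    p, masses = aggregate_isotopologues(comp)
    keep = p >= prune * p.max()
    keep &= p > 0
    mz = np.array([ion_mz(m, z) for m in masses[keep]])
    ab = p[keep] / p[keep].max()
    order = np.argsort(mz)
    return IsotopePattern(z, mz[order], ab[order], origin="theoretical")


def mixture_grid_width(z: int) -> float:
    """Shared-grid bin width for mixing/fitting two envelopes at charge z
    (well under half the 1.0034/z isotopologue spacing)."""
    return 0.2 / z


def bin_on_grid(pattern: IsotopePattern, grid_keys: np.ndarray, width: float):
    """Sum pattern abundance into the given integer grid bins."""
    keys = np.round(pattern.mz / width).astype(int)
    out = np.zeros(grid_keys.size)
    for k, a in zip(keys, pattern.abundance):
        idx = np.searchsorted(grid_keys, k)
        if idx < grid_keys.size and grid_keys[idx] == k:
            out[idx] += a
    return out


def shared_grid(patterns, width: float) -> np.ndarray:
    """Sorted union of integer bin keys occupied by any of the patterns."""
    keys = set()
    for p in patterns:
        keys.update(np.round(p.mz / width).astype(int).tolist())
    return np.array(sorted(keys))


def mixture_distribution(
    a: IsotopePattern, b: IsotopePattern, f: float
) -> IsotopePattern:
    """Mix two same-charge envelopes: (1-f)*a + f*b on a shared m/z grid,
    max-renormalized.  ``f`` is the fraction of ``b``."""
    if a.charge != b.charge:
        raise ValueError(f"charge mismatch: {a.charge} vs {b.charge}")
    if not 0.0 <= f <= 1.0:
        raise ValueError(f"mixing fraction must be in [0, 1], got {f}")
    width = mixture_grid_width(a.charge)
    keys_a = np.round(a.mz / width).astype(int)
    keys_b = np.round(b.mz / width).astype(int)
    acc: dict[int, list[float]] = {}
    for keys, pat, w in ((keys_a, a, 1.0 - f), (keys_b, b, f)):
        for k, mz, ab in zip(keys, pat.mz, pat.abundance):
            entry = acc.setdefault(int(k), [0.0, 0.0])
            entry[0] += w * ab
            entry[1] += w * ab * mz
    keys_sorted = sorted(k for k, (ab, _) in acc.items() if ab > 0)
    ab = np.array([acc[k][0] for k in keys_sorted])
    mz = np.array([acc[k][1] / acc[k][0] for k in keys_sorted])
    ab = ab / ab.max()
    return IsotopePattern(a.charge, mz, ab, origin="theoretical")
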