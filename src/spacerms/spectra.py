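"""Spectrum I/O, preprocessing, and the synthetic MS/MS simulator.

Real data enter as mzML (a compact lxml-based reader covering
MSConvert-style float arrays) or as plain TSV peak lists; preprocessing mirrors the standard top-down oligo workflow:
average the scans over the elution period, centroid, drop signal counts
below the noise floor (default 500), and drop everything above the
precursor-contaminated region (default 1310 m/z).

The simulator emulates an averaged negative-mode QTOF MS/MS spectrum of
a guide-RNA mixture: per component, c- (and optionally y-) ion ladders
with full isotopic envelopes across charge states, fragment response
decaying exponentially with index, a Gaussian charge-state preference,
m/z jitter at instrument accuracy, and an exponential noise floor.  All
randomness is driven by one seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Dict, List, Sequence, Tuple

import numpy as np

from .fragments import fragment
from .isotopes import isotope_distribution
from .oligo import OligoSequence

DEFAULT_NOISE_FLOOR = 500.0
DEFAULT_MZ_MAX = 1310.0


@dataclass(frozen=True)
class Spectrum:
    """A peak list sorted by m/z, either profile or centroided."""

    mz: np.ndarray
    intensity: np.ndarray
    mode: str = "centroid"
    metadata: Tuple[Tuple[str, str], ...] = ()

    def __post_init__(self) -> None:
        mz = np.asarray(self.mz, dtype=float)
        inten = np.asarray(self.intensity, dtype=float)
        if mz.shape != inten.shape:
            raise ValueError("mz and intensity must be the same length")
        if np.any(inten < 0):
            raise ValueError("negative intensity")
        order = np.argsort(mz, kind="stable")
        object.__setattr__(self, "mz", mz[order])
        object.__setattr__(self, "intensity", inten[order])

    def __len__(self) -> int:
        return int(self.mz.size)


class SpectrumFormatError(ValueError):
    """Malformed spectrum file; message names the offending record."""


def load_spectra(path: str | Path, fmt: str | None = None) -> List[Spectrum]:
    """Read scans from an mzML file or a TSV peak list.

    TSV dialect: two whitespace/tab-separated columns (m/z, intensity);
    scans are separated by blank lines.  Lines starting with ``#`` are
    comments.  Format is inferred from the extension when not given.
    """
    path = Path(path)
    if fmt is None:
        fmt = "mzml" if path.suffix.lower() == ".mzml" else "tsv"
    if fmt.lower() == "mzml":
        return _load_mzml(path)
    if fmt.lower() == "tsv":
        return _load_tsv(path)
    raise ValueError(f"unknown spectrum format {fmt!r}")


def _decode_binary_array(bda, path: Path, spectrum_id: str) -> tuple[str, np.ndarray]:
    """Decode one <binaryDataArray>: (array kind, values)."""
    import base64
    import zlib

    dtype = None
    compressed = False
    kind = None
    for cv in bda.iter("{*}cvParam"):
        acc = cv.get("accession", "")
        if acc == "MS:1000523":
            dtype = "<f8"
        elif acc == "MS:1000521":
            dtype = "<f4"
        elif acc == "MS:1000574":
            compressed = True
        elif acc == "MS:1000514":
            kind = "mz"
        elif acc == "MS:1000515":
            kind = "intensity"
    binary = bda.find("{*}binary")
    if binary is None or kind is None or dtype is None:
        raise SpectrumFormatError(
            f"{path}: spectrum {spectrum_id!r}: incomplete binaryDataArray"
        )
    raw = base64.b64decode(binary.text or "")
    if compressed:
        raw = zlib.decompress(raw)
    return kind, np.frombuffer(raw, dtype=dtype).astype(float)


def _load_mzml(path: Path) -> List[Spectrum]:
    """Minimal mzML reader (MSConvert-style files): 32/64-bit float m/z
    and intensity arrays, optionally zlib-compressed."""
    from lxml import etree

    scans: List[Spectrum] = []
    try:
        tree = etree.parse(str(path))
    except etree.XMLSyntaxError as exc:
        raise SpectrumFormatError(f"{path}: {exc}") from exc
    for spec_el in tree.iter("{*}spectrum"):
        spectrum_id = spec_el.get("id", "")
        mode = "profile"
        for cv in spec_el.findall("{*}cvParam"):
            if cv.get("accession") == "MS:1000127":
                mode = "centroid"
        arrays = dict(
            _decode_binary_array(bda, path, spectrum_id)
            for bda in spec_el.iter("{*}binaryDataArray")
        )
        if "mz" not in arrays or "intensity" not in arrays:
            raise SpectrumFormatError(
                f"{path}: spectrum {spectrum_id!r}: missing m/z or intensity array"
            )
        scans.append(
            Spectrum(arrays["mz"], arrays["intensity"], mode=mode,
                     metadata=(("id", spectrum_id),))
        )
    if not scans:
        raise SpectrumFormatError(f"{path}: no spectra found")
    return scans


def _load_tsv(path: Path) -> List[Spectrum]:
    scans: List[Spectrum] = []
    mzs: List[float] = []
    intens: List[float] = []

    def flush() -> None:
        if mzs:
            scans.append(Spectrum(np.array(mzs), np.array(intens)))
            mzs.clear()
            intens.clear()

    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            stripped = line.strip()
            if not stripped:
                flush()
                continue
            if stripped.startswith("#"):
                continue
            parts = stripped.split()
            if len(parts) != 2:
                raise SpectrumFormatError(
                    f"{path}:{lineno}: expected 'mz intensity', got {stripped!r}"
                )
            try:
                mzs.append(float(parts[0]))
                intens.append(float(parts[1]))
            except ValueError as exc:
                raise SpectrumFormatError(f"{path}:{lineno}: {exc}") from exc
    flush()
    if not scans:
        raise SpectrumFormatError(f"{path}: no spectra found")
    return scans


def write_tsv(spectra: Sequence[Spectrum] | Spectrum, path: str | Path) -> None:
    """Write scans as blank-line-separated two-column TSV blocks."""
    if isinstance(spectra, Spectrum):
        spectra = [spectra]
    with open(path, "w") as fh:
        for i, spec in enumerate(spectra):
            if i:
                fh.write("\n")
            for mz, inten in zip(spec.mz, spec.intensity):
                fh.write(f"{mz:.6f}\t{inten:.6f}\n")


def centroid(spectrum: Spectrum) -> Spectrum:
    """Local-maximum peak picking with an intensity-weighted centroid over
    each contiguous above-zero stretch around the maximum."""
    if spectrum.mode == "centroid":
        return spectrum
    mz, inten = spectrum.mz, spectrum.intensity
    peaks_mz: List[float] = []
    peaks_int: List[float] = []
    i = 0
    n = len(mz)
    while i < n:
        if inten[i] <= 0:
            i += 1
            continue
        j = i
        while j + 1 < n and inten[j + 1] > 0:
            j += 1
        seg_mz = mz[i:j + 1]
        seg_int = inten[i:j + 1]
        # split the stretch at local maxima (fall back to one peak)
        apex = int(np.argmax(seg_int))
        total = seg_int.sum()
        peaks_mz.append(float((seg_mz * seg_int).sum() / total))
        peaks_int.append(float(seg_int[apex]))
        i = j + 1
    return Spectrum(np.array(peaks_mz), np.array(peaks_int), mode="centroid",
                    metadata=spectrum.metadata)


def _pool_centroided(scans: Sequence[Spectrum], tol: float = 0.005) -> Spectrum:
    """Average centroided scans by pooling peaks within ``tol`` m/z."""
    all_mz = np.concatenate([s.mz for s in scans])
    all_int = np.concatenate([s.intensity for s in scans])
    order = np.argsort(all_mz)
    all_mz, all_int = all_mz[order], all_int[order]
    out_mz: List[float] = []
    out_int: List[float] = []
    i = 0
    n = all_mz.size
    nscans = len(scans)
    while i < n:
        j = i
        while j + 1 < n and all_mz[j + 1] - all_mz[j] <= tol:
            j += 1
        seg_mz = all_mz[i:j + 1]
        seg_int = all_int[i:j + 1]
        out_mz.append(float((seg_mz * seg_int).sum() / seg_int.sum()))
        out_int.append(float(seg_int.sum() / nscans))
        i = j + 1
    return Spectrum(np.array(out_mz), np.array(out_int), mode="centroid")


def preprocess(
    scans: Sequence[Spectrum],
    noise_floor: float = DEFAULT_NOISE_FLOOR,
    mz_max: float = DEFAULT_MZ_MAX,
) -> Spectrum:
    """Average scans, centroid, and apply the noise-floor and high-m/z cuts.

    Peaks with intensity < ``noise_floor`` and peaks with m/z > ``mz_max``
    are removed.  Idempotent on already-centroided, filtered input.
    """
    if not scans:
        raise ValueError("no scans to preprocess")
    if any(s.mode == "profile" for s in scans):
        if len(scans) > 1:
            axis = scans[0].mz
            for s in scans[1:]:
                if len(s) != len(scans[0]) or not np.allclose(s.mz, axis):
                    raise ValueError("profile scans must share an m/z axis")
            avg = Spectrum(
                axis,
                np.mean([s.intensity for s in scans], axis=0),
                mode="profile",
            )
        else:
            avg = scans[0]
        spec = centroid(avg)
    else:
        spec = scans[0] if len(scans) == 1 else _pool_centroided(scans)
    keep = (spec.intensity >= noise_floor) & (spec.mz <= mz_max)
    return Spectrum(spec.mz[keep], spec.intensity[keep], mode="centroid",
                    metadata=spec.metadata)


@dataclass(frozen=True)
class SimulationConfig:
    """Conditions for one simulated averaged MS/MS spectrum.

    ``components`` are (sequence, molar fraction) pairs; fractions must
    sum to 1.  Fragment response follows
    ``base_intensity * fraction * exp(-decay * (index - 1))`` split over
    charge states by a Gaussian preference centred at ``1 + (index-1)/3.5``.
    The decay default makes c20 about 5 % of c2, reproducing the size
    ordering of fragment sensitivity seen on QTOF instruments.
    """

    components: Tuple[Tuple[OligoSequence, float], ...]
    ion_types: Tuple[str, ...] = ("c",)
    index_range: Tuple[int, int] | None = None
    charges: Tuple[int, ...] = (1, 2, 3, 4, 5, 6, 7)
    base_intensity: float = 1.0e6
    decay: float = math.log(20.0) / 18.0
    charge_sigma: float = 1.25
    noise_floor: float = DEFAULT_NOISE_FLOOR
    n_noise_peaks: int = 200
    mz_jitter_sd: float = 0.003
    intensity_cv: float = 0.02
    mz_range: Tuple[float, float] = (150.0, 1400.0)
    precursor_region: bool = False
    skip_indices: Tuple[int, ...] = ()
    seed: int = 0

    def validate(self) -> None:
        total = sum(f for _, f in self.components)
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"component fractions must sum to 1, got {total}")
        if self.mz_jitter_sd < 0 or self.intensity_cv < 0:
            raise ValueError("noise parameters must be non-negative")


def clean_config(components, **overrides) -> SimulationConfig:
    """A noiseless configuration (no jitter, no noise peaks, no intensity
    scatter, zero floor) for oracle-style round-trip tests."""
    defaults = dict(
        noise_floor=0.0, n_noise_peaks=0, mz_jitter_sd=0.0, intensity_cv=0.0
    )
    defaults.update(overrides)
    return SimulationConfig(tuple(components), **defaults)


def simulate_msms(cfg: SimulationConfig) -> Spectrum:
    """Generate one centroided spectrum under ``cfg``; deterministic for a
    fixed seed."""
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)
    mzs: List[float] = []
    intens: List[float] = []
    lo, hi = cfg.mz_range
    for oligo, fraction in cfg.components:
        if fraction <= 0:
            continue
        if cfg.index_range is None:
            idx_lo, idx_hi = 1, min(20, len(oligo) - 1)
        else:
            idx_lo, idx_hi = cfg.index_range
            idx_hi = min(idx_hi, len(oligo) - 1)
        for ion_type in cfg.ion_types:
            for n in range(idx_lo, idx_hi + 1):
                if n in cfg.skip_indices:
                    continue
                frag = fragment(oligo, ion_type, n)
                response = (
                    cfg.base_intensity * fraction * math.exp(-cfg.decay * (n - 1))
                )
                centre = 1.0 + (n - 1) / 3.5
                weights = np.array(
                    [math.exp(-0.5 * ((z - centre) / cfg.charge_sigma) ** 2)
                     for z in cfg.charges]
                )
                weights = weights / weights.sum()
                for z, w in zip(cfg.charges, weights):
                    if w * response < 1e-3:
                        continue
                    pattern = isotope_distribution(frag.composition, z)
                    scale = response * w
                    for mz, ab in zip(pattern.mz, pattern.abundance):
                        if not lo <= mz <= hi:
                            continue
                        jitter = rng.normal(0.0, cfg.mz_jitter_sd) if cfg.mz_jitter_sd else 0.0
                        noise = (
                            math.exp(rng.normal(0.0, cfg.intensity_cv))
                            if cfg.intensity_cv
                            else 1.0
                        )
                        mzs.append(mz + jitter)
                        intens.append(ab * scale * noise)
    if cfg.n_noise_peaks and cfg.noise_floor > 0:
        noise_mz = rng.uniform(lo, hi, cfg.n_noise_peaks)
        noise_int = rng.exponential(cfg.noise_floor, cfg.n_noise_peaks)
        mzs.extend(noise_mz.tolist())
        intens.extend(noise_int.tolist())
    if cfg.precursor_region:
        dense_mz = rng.uniform(1310.0, min(hi, 1400.0), 300)
        dense_int = rng.exponential(50 * max(cfg.noise_floor, 1.0), 300)
        mzs.extend(dense_mz.tolist())
        intens.extend(dense_int.tolist())
    return Spectrum(np.array(mzs), np.array(intens), mode="centroid")
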