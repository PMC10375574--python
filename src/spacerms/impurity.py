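"""Single-base substitution discovery, site quantitation, and C<->U
isotope-mixture fitting.

Discovery scores every single-base permutation of the spacer by the
intensity and isotopic fidelity of the c-fragments unique to it
(c_n..c_m for a substitution at n, m the spacer end):

    score = (unique-region coverage)^2 * sum_matched(abundance * cosine^2)

C<->U substitutions shift a fragment by only +-0.984 Da, so the 13C
isotopologue of the C form interferes with the monoisotopic peak of the
U form (-0.019 Da offset).  They are excluded from discovery and
handled by fitting the observed envelope as a two-component mixture of
the parent and substitute theoretical distributions: non-negative least
squares for the initial fraction, then a one-dimensional refinement
minimizing the cosine distance.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Iterable, List, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy.optimize import minimize_scalar, nnls

from .chem import Composition
from .fragments import c_fragment
from .isotopes import (
    IsotopePattern,
    bin_on_grid,
    isotope_distribution,
    mixture_grid_width,
    shared_grid,
)
from .matching import (
    DEFAULT_MIN_CONSECUTIVE,
    DEFAULT_MIN_COSINE,
    DEFAULT_TOL,
    SPACER_CHARGES,
    FragmentMatch,
    cosine_score,
    match_fragment,
    match_pattern,
)
from .oligo import OligoSequence, enumerate_substitutions
from .spectra import Spectrum

#: composition delta of a U -> C substitution (O replaced by NH)
U_TO_C = (
    Composition.from_dict({"N": 1, "H": 1}),
    Composition.from_dict({"O": 1}),
)


@dataclass(frozen=True)
class SubstitutionCandidate:
    """One scored single-base substitution hypothesis."""

    position: int
    from_base: str
    to_base: str
    score: float
    coverage: float                      # fraction of unique c_n..c_m covered
    matches: Tuple[FragmentMatch, ...]

    @property
    def label(self) -> str:
        return f"{self.position} {self.from_base}>{self.to_base}"


def score_substitutions(
    spectrum: Spectrum,
    parent: OligoSequence,
    region: Tuple[int, int] | None = None,
    exclude_cu: bool = True,
    charges: Iterable[int] = SPACER_CHARGES,
    tol: float = DEFAULT_TOL,
    min_cosine: float = DEFAULT_MIN_COSINE,
) -> List[SubstitutionCandidate]:
    """Score and rank every single-base substitution of the spacer.

    For each candidate only the c-fragments whose composition differs
    from the parent's are informative: c_n..c_m for a substitution at
    position n, with m the region end.  Candidates are returned in
    descending score order.
    """
    if region is None:
        region = (1, min(20, len(parent) - 1))
    lo, hi = region
    charges = tuple(charges)
    out: List[SubstitutionCandidate] = []
    for position, from_base, to_base, variant in enumerate_substitutions(
        parent, region, exclude_cu=exclude_cu
    ):
        unique_indices = range(position, hi + 1)
        total = 0.0
        covered = 0
        all_matches: List[FragmentMatch] = []
        for n in unique_indices:
            frag = c_fragment(variant, n)
            hit = False
            for z in charges:
                m = match_fragment(
                    spectrum, frag, z, tol=tol, min_cosine=min_cosine
                )
                if m is not None:
                    hit = True
                    total += m.abundance * m.cosine**2
                    all_matches.append(m)
            covered += hit
        n_unique = hi - position + 1
        coverage = covered / n_unique if n_unique else 0.0
        out.append(
            SubstitutionCandidate(
                position, from_base, to_base,
                coverage**2 * total, coverage, tuple(all_matches),
            )
        )
    out.sort(key=lambda c: (-c.score, c.position, c.to_base))
    return out


def max_score_by_type(
    candidates: Sequence[SubstitutionCandidate],
) -> Dict[Tuple[str, str], float]:
    """The per-substitution-type maximum score (position ignored), the
    headline view when isomeric positions share fragment masses."""
    best: Dict[Tuple[str, str], float] = {}
    for c in candidates:
        key = (c.from_base, c.to_base)
        best[key] = max(best.get(key, 0.0), c.score)
    return best


def candidates_frame(candidates: Sequence[SubstitutionCandidate]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "position": c.position,
                "from_base": c.from_base,
                "to_base": c.to_base,
                "score": c.score,
                "coverage": c.coverage,
                "n_matches": len(c.matches),
            }
            for c in candidates
        ]
    )


@dataclass(frozen=True)
class SitePercent:
    """Per-position variant fraction from c-ion abundance ratios."""

    position: int
    percent: float | None
    flag: str   # "ok", "indistinguishable", "undefined"


def quantify_variant_sites(
    spectrum: Spectrum,
    parent: OligoSequence,
    variant: OligoSequence,
    positions: Iterable[int],
    charges: Iterable[int] = SPACER_CHARGES,
    tol: float = DEFAULT_TOL,
    min_cosine: float = DEFAULT_MIN_COSINE,
) -> List[SitePercent]:
    """Variant percentage at each position n:
    100 * A_variant(c_n) / (A_variant(c_n) + A_parent(c_n)), abundances
    summed over all matched charge states.

    Positions where parent and variant c_n have the same mass are
    flagged ``indistinguishable``; positions with no signal for either
    species are flagged ``undefined``.
    """
    charges = tuple(charges)
    out: List[SitePercent] = []
    for n in positions:
        frag_p = c_fragment(parent, n)
        frag_v = c_fragment(variant, n)
        if abs(frag_p.neutral_mono_mass - frag_v.neutral_mono_mass) < 1e-6:
            out.append(SitePercent(n, None, "indistinguishable"))
            continue
        a_parent = a_variant = 0.0
        for z in charges:
            mp = match_fragment(spectrum, frag_p, z, tol=tol, min_cosine=min_cosine)
            if mp is not None:
                a_parent += mp.abundance
            mv = match_fragment(spectrum, frag_v, z, tol=tol, min_cosine=min_cosine)
            if mv is not None:
                a_variant += mv.abundance
        total = a_parent + a_variant
        if total == 0:
            out.append(SitePercent(n, None, "undefined"))
        else:
            out.append(SitePercent(n, 100.0 * a_variant / total, "ok"))
    return out


@dataclass(frozen=True)
class MixtureFit:
    """Result of fitting an observed envelope as parent + substitute."""

    fraction_substitute: float
    cosine: float
    residuals: np.ndarray   # observed minus fitted, both max-normalized


def _binned_columns(parent_pat: IsotopePattern, sub_pat: IsotopePattern):
    width = mixture_grid_width(parent_pat.charge)
    grid = shared_grid((parent_pat, sub_pat), width)
    col_p = bin_on_grid(parent_pat, grid, width)
    col_s = bin_on_grid(sub_pat, grid, width)
    return grid, width, col_p, col_s


def fit_cu_mixture(
    observed: IsotopePattern,
    parent_comp: Composition,
    substitute_comp: Composition,
) -> MixtureFit:
    """Two-stage C<->U mixture deconvolution of one observed envelope.

    Stage 1: non-negative least squares of the observed abundances on
    the two theoretical patterns binned to a shared grid.  Stage 2:
    bounded scalar refinement of the substitute fraction minimizing the
    cosine distance between the mixed theoretical envelope and the
    observation.
    """
    z = observed.charge
    pat_p = isotope_distribution(parent_comp, z)
    pat_s = isotope_distribution(substitute_comp, z)
    grid, width, col_p, col_s = _binned_columns(pat_p, pat_s)
    if np.allclose(col_p, col_s):
        raise ValueError("degenerate design: parent and substitute patterns coincide")
    obs = bin_on_grid(observed, grid, width)
    design = np.column_stack([col_p, col_s])
    coef, _ = nnls(design, obs)
    total = coef.sum()
    f0 = float(coef[1] / total) if total > 0 else 0.0

    def mix(f: float) -> np.ndarray:
        return (1.0 - f) * col_p + f * col_s

    def cos_dist(f: float) -> float:
        return 1.0 - cosine_score(mix(f), obs)

    res = minimize_scalar(
        cos_dist, bounds=(0.0, 1.0), method="bounded",
        options={"xatol": 1e-5},
    )
    f = float(res.x)
    # keep whichever of the nnls seed / refinement fits better
    if cos_dist(f0) < cos_dist(f):
        f = f0
    fitted = mix(f)
    cos = cosine_score(fitted, obs)
    obs_n = obs / obs.max() if obs.max() > 0 else obs
    fit_n = fitted / fitted.max() if fitted.max() > 0 else fitted
    return MixtureFit(f, cos, obs_n - fit_n)


def cu_substitute_composition(comp: Composition, direction: str) -> Composition:
    """Composition after one U->C ('u_to_c') or C->U ('c_to_u') swap."""
    add, sub = U_TO_C
    if direction == "u_to_c":
        return (comp + add) - sub
    if direction == "c_to_u":
        return (comp + sub) - add
    raise ValueError(f"unknown direction {direction!r}")


def extract_envelope(
    spectrum: Spectrum,
    theoretical_mz: np.ndarray,
    z: int,
    tol: float = DEFAULT_TOL,
    min_peaks: int = DEFAULT_MIN_CONSECUTIVE,
) -> IsotopePattern | None:
    """Observed envelope near a set of theoretical positions.

    Each spectrum peak within ``tol`` of any theoretical m/z is taken
    once (peak-centric, so overlapping C/U envelopes never double-count
    a peak).  Returns None when fewer than ``min_peaks`` peaks are found.
    """
    theo = np.sort(np.asarray(theoretical_mz, dtype=float))
    sel = []
    for j in range(len(spectrum)):
        mz = spectrum.mz[j]
        i = int(np.searchsorted(theo, mz))
        near = min(
            (abs(theo[k] - mz) for k in (i - 1, i) if 0 <= k < theo.size),
            default=np.inf,
        )
        if near <= tol:
            sel.append(j)
    if len(sel) < min_peaks:
        return None
    sel_arr = np.array(sel)
    mzs, first = np.unique(spectrum.mz[sel_arr], return_index=True)
    return IsotopePattern(
        z, mzs, spectrum.intensity[sel_arr][first], origin="observed"
    )


@dataclass(frozen=True)
class CuSiteEstimate:
    position: int
    percent: float
    fit_cosine: float
    n_charges: int

    @property
    def low_confidence(self) -> bool:
        return self.fit_cosine < 0.95


def cu_profile(
    spectrum: Spectrum,
    parent: OligoSequence,
    region: Tuple[int, int] | None = None,
    charges: Iterable[int] = SPACER_CHARGES,
    tol: float = DEFAULT_TOL,
) -> Dict[str, Dict[int, CuSiteEstimate]]:
    """Position-by-position C>U and U>C substitute fractions across the
    spacer c-ion ladder.

    For every c_n (n in the region) and every charge where the parent
    envelope has detectable signal, the observed envelope is fitted as a
    mixture of the parent and the one-swap substitute.  Per position the
    reported fraction comes from the charge state with the best fit
    cosine: envelopes contaminated by co-occurring fragments (spectral
    congestion) fit visibly worse, so the cleanest charge is the most
    trustworthy; fits below the 0.80 acceptance cosine are discarded
    outright.  Keys are 'u_to_c' and 'c_to_u'; positions lacking the
    required base are absent.
    """
    if region is None:
        region = (1, min(20, len(parent) - 1))
    lo, hi = region
    charges = tuple(charges)
    out: Dict[str, Dict[int, CuSiteEstimate]] = {"u_to_c": {}, "c_to_u": {}}
    for n in range(lo, hi + 1):
        prefix = parent.nucleotides[:n]
        has_u = any(nt.base == "U" for nt in prefix)
        has_c = any(nt.base == "C" for nt in prefix)
        frag = c_fragment(parent, n)
        for direction, applicable in (("u_to_c", has_u), ("c_to_u", has_c)):
            if not applicable:
                continue
            sub_comp = cu_substitute_composition(frag.composition, direction)
            fractions: List[float] = []
            cosines: List[float] = []
            for z in charges:
                pat_p = isotope_distribution(frag.composition, z)
                pat_s = isotope_distribution(sub_comp, z)
                obs_pat = extract_envelope(
                    spectrum, np.concatenate([pat_p.mz, pat_s.mz]), z, tol
                )
                if obs_pat is None:
                    continue
                try:
                    fit = fit_cu_mixture(obs_pat, frag.composition, sub_comp)
                except ValueError:
                    continue
                if fit.cosine < DEFAULT_MIN_COSINE:
                    continue
                fractions.append(fit.fraction_substitute)
                cosines.append(fit.cosine)
            if fractions:
                best = int(np.argmax(cosines))
                out[direction][n] = CuSiteEstimate(
                    n,
                    100.0 * fractions[best],
                    cosines[best],
                    len(fractions),
                )
    return out


def mean_cu_percent(
    profile: Dict[int, CuSiteEstimate], start: int, end: int
) -> float:
    """Mean substitute percentage over positions start..end (a summary
    for a designated substitution site: the plateau from the site to the
    spacer end)."""
    vals = [e.percent for n, e in profile.items() if start <= n <= end]
    return float(np.mean(vals)) if vals else float("nan")


def spike_in_series(
    parent: OligoSequence,
    variant: OligoSequence,
    fractions: Sequence[float],
    positions: Sequence[int],
    seed: int = 0,
    sim_kwargs: dict | None = None,
    preprocess_kwargs: dict | None = None,
) -> pd.DataFrame:
    """Simulate spike-ins of ``variant`` into ``parent`` at the given
    molar fractions, quantify per position, and tabulate measured vs
    actual percent (a calibration-linearity runner).
    """
    from .spectra import SimulationConfig, preprocess, simulate_msms

    sim_kwargs = dict(sim_kwargs or {})
    preprocess_kwargs = dict(preprocess_kwargs or {})
    rows = []
    for i, frac in enumerate(fractions):
        cfg = SimulationConfig(
            components=((parent, 1.0 - frac), (variant, frac)),
            seed=seed + i,
            **sim_kwargs,
        )
        spec = preprocess([simulate_msms(cfg)], **preprocess_kwargs)
        for site in quantify_variant_sites(spec, parent, variant, positions):
            rows.append(
                {
                    "actual_percent": 100.0 * frac,
                    "position": site.position,
                    "measured_percent": site.percent,
                    "flag": site.flag,
                }
            )
    return pd.DataFrame(rows)


def linearity_r2(table: pd.DataFrame) -> Dict[int, float]:
    """Per-position ordinary-least-squares R^2 of measured vs actual
    percent from a :func:`spike_in_series` table.  Undetected variant
    levels count as 0 %."""
    out: Dict[int, float] = {}
    for position, grp in table.groupby("position"):
        grp = grp[grp["flag"] != "indistinguishable"]
        if len(grp) < 3:
            continue
        x = grp["actual_percent"].to_numpy(dtype=float)
        y = grp["measured_percent"].fillna(0.0).to_numpy(dtype=float)
        slope, intercept = np.polyfit(x, y, 1)
        pred = slope * x + intercept
        ss_res = float(np.sum((y - pred) ** 2))
        ss_tot = float(np.sum((y - y.mean()) ** 2))
        out[int(position)] = 1.0 - ss_res / ss_tot if ss_tot > 0 else float("nan")
    return out
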