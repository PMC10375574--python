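"""End-to-end spacer QC orchestration and reproducible reports.

`run_spacer_qc` composes the pipeline stages — preprocess, spacer
coverage, decoy FDR, substitution discovery, C/U profile, optional de
novo — under one configuration object whose defaults are the standard
workflow thresholds (0.01 m/z tolerance, 0.80 cosine, 500-count noise
floor, 1310 m/z cutoff).  Reports serialize to JSON (summary) and TSV
(fragment table) and regenerate bit-identically from the same inputs.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Tuple

import numpy as np

from . import __version__
from .denovo import Scaffold, candidates_frame as denovo_frame, denovo_spacer
from .impurity import (
    candidates_frame as substitution_frame,
    cu_profile,
    max_score_by_type,
    score_substitutions,
)
from .matching import estimate_fdr, spacer_coverage
from .oligo import OligoSequence, parse_sequence
from .spectra import (
    DEFAULT_MZ_MAX,
    DEFAULT_NOISE_FLOOR,
    Spectrum,
    load_spectra,
    preprocess,
)


@dataclass(frozen=True)
class AnalysisConfig:
    """Pipeline thresholds; defaults are the standard workflow values."""

    tol: float = 0.01
    min_cosine: float = 0.80
    noise_floor: float = DEFAULT_NOISE_FLOOR
    mz_max: float = DEFAULT_MZ_MAX
    spacer_charges: Tuple[int, ...] = (1, 2, 3, 4, 5, 6, 7)
    full_charges: Tuple[int, ...] = tuple(range(1, 26))
    fdr_offset_max: float = 1000.0
    fdr_step: float = 50.0
    exclude_cu: bool = True
    run_denovo: bool = False
    seed: int = 0

    def to_dict(self) -> Dict:
        d = dataclasses.asdict(self)
        d["spacer_charges"] = list(self.spacer_charges)
        d["full_charges"] = list(self.full_charges)
        return d


@dataclass
class QcReport:
    """Self-contained QC result; regenerates identically from the same
    inputs, configuration, and seed."""

    sequence_name: str
    config: AnalysisConfig
    spacer_coverage_percent: float
    n_matched_fragments: int
    fdr: float
    fdr_target_hits: int
    top_substitutions: List[Dict]
    substitution_type_max: Dict[str, float]
    cu_profile: Dict[str, Dict[int, float]]
    denovo_top: List[Dict]
    version: str = ""

    def to_json_dict(self) -> Dict:
        return {
            "schema_version": 1,
            "tool_version": self.version,
            "sequence": self.sequence_name,
            "config": self.config.to_dict(),
            "spacer_coverage_percent": self.spacer_coverage_percent,
            "n_matched_fragments": self.n_matched_fragments,
            "fdr": None if np.isnan(self.fdr) else self.fdr,
            "fdr_target_hits": self.fdr_target_hits,
            "top_substitutions": self.top_substitutions,
            "substitution_type_max": self.substitution_type_max,
            "cu_profile": self.cu_profile,
            "denovo_top": self.denovo_top,
        }


def run_spacer_qc(
    spectra_path: str | Path | Spectrum,
    sequence: str | OligoSequence,
    config: AnalysisConfig | None = None,
    out_dir: str | Path | None = None,
) -> QcReport:
    """Run the full spacer QC pipeline on one averaged MS/MS acquisition.

    ``spectra_path`` may be an mzML/TSV path (scans are averaged and
    preprocessed) or an already-preprocessed :class:`Spectrum`.
    """
    config = config or AnalysisConfig()
    if isinstance(sequence, str):
        oligo = parse_sequence(sequence, name="query")
    else:
        oligo = sequence
    if isinstance(spectra_path, Spectrum):
        spec = spectra_path
    else:
        scans = load_spectra(spectra_path)
        spec = preprocess(scans, noise_floor=config.noise_floor, mz_max=config.mz_max)

    cov = spacer_coverage(
        spec, oligo, tol=config.tol, min_cosine=config.min_cosine,
        charges=config.spacer_charges,
    )
    n_matched = sum(
        len(ms) for by_index in cov.matches.values() for ms in by_index.values()
    )
    fdr = estimate_fdr(
        spec, oligo, charges=config.spacer_charges,
        offset_max=config.fdr_offset_max, step=config.fdr_step,
        tol=config.tol, min_cosine=config.min_cosine,
    )
    subs = score_substitutions(
        spec, oligo, exclude_cu=config.exclude_cu,
        charges=config.spacer_charges, tol=config.tol,
        min_cosine=config.min_cosine,
    )
    top_subs = [
        {
            "position": c.position,
            "from": c.from_base,
            "to": c.to_base,
            "score": c.score,
            "coverage": c.coverage,
        }
        for c in subs[:10]
    ]
    type_max = {
        f"{a}>{b}": score for (a, b), score in max_score_by_type(subs).items()
    }
    profile = cu_profile(
        spec, oligo, charges=config.spacer_charges, tol=config.tol
    )
    profile_out = {
        direction: {int(n): est.percent for n, est in by_pos.items()}
        for direction, by_pos in profile.items()
    }
    denovo_top: List[Dict] = []
    if config.run_denovo:
        cands = denovo_spacer(
            spec, Scaffold.from_oligo(oligo), charges=config.spacer_charges,
            tol=config.tol, min_cosine=config.min_cosine,
        )
        denovo_top = denovo_frame(cands[:10]).to_dict(orient="records")

    report = QcReport(
        sequence_name=oligo.name,
        config=config,
        spacer_coverage_percent=cov.percent,
        n_matched_fragments=n_matched,
        fdr=fdr.fdr,
        fdr_target_hits=fdr.target_hits,
        top_substitutions=top_subs,
        substitution_type_max=type_max,
        cu_profile=profile_out,
        denovo_top=denovo_top,
        version=__version__,
    )
    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        with open(out_dir / "qc_report.json", "w") as fh:
            json.dump(report.to_json_dict(), fh, indent=2, sort_keys=True)
        cov.to_frame().to_csv(out_dir / "matched_fragments.tsv", sep="\t", index=False)
        substitution_frame(subs).to_csv(
            out_dir / "substitution_candidates.tsv", sep="\t", index=False
        )
    return report
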