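# spacerms

Top-down MS/MS characterization of chemically modified guide RNA.

Single-guide RNAs (sgRNA) for CRISPR therapeutics are ~100-mer synthetic
RNAs whose first 20 nucleotides — the *spacer* — set the genomic target.
A single base substitution in the spacer can redirect editing, so spacer
fidelity is a critical quality attribute. `spacerms` analyzes averaged
negative-mode QTOF MS/MS spectra of intact guides, where collisional
activation cleaves the backbone P–O5′ bond into complementary *c*-ions
(5′ fragment keeping the cleavage-site phosphate or phosphorothioate)
and *y*-ions (3′ fragment with a free 5′-OH). The *c*₁..*c*₂₀ ladder
reads the spacer directly, chemical modifications included.

The package provides:

* **Mass/fragment/isotope engine** — parse the `N`/`N(m)`/`N(ms)` token
  syntax for 2′-O-methyl and phosphorothioate chemistry, compute
  elemental compositions, monoisotopic/average masses, c/y-fragment m/z
  at any charge, and nucleon-binned isotopologue distributions by
  per-element convolution.
* **Spectrum handling** — mzML/TSV reading, scan averaging, centroiding,
  noise-floor (500 counts) and high-m/z (1310) filtering, plus a seeded
  simulator of averaged guide-mixture MS/MS spectra for testing every
  downstream stage without instrument data.
* **Matching** — fragment assignment requiring mass error < 0.01 m/z,
  ≥ 2 consecutive isotopologues, and isotopic cosine > 0.80; sequence
  coverage reports; decoy FDR from ±1000 ppm mass-offset searches.
* **Impurity analysis** — discovery and ranking of all n×3 single-base
  spacer substitutions scored by
  `coverage² · Σ abundance · cosine²` over the substitution-specific
  fragments; per-site variant quantitation from c-ion abundance ratios;
  and C↔U substitution quantitation by NNLS + cosine-refined fitting of
  the overlapping isotope envelopes (the two forms differ by 0.984 Da
  with a −0.019 Da ¹³C interference).
* **De novo sequencing** — breadth-first spacer read-out from the c-ion
  ladder over a modification scaffold, low-abundance impurity tags with
  a missed-fragment budget, and modification placement (2′-O-methyl /
  phosphorothioate) out to position 28 with stretch-level localization
  when a flanking fragment is missing.

## Worked example

```python
from spacerms import (
    reference_sequence, elemental_composition, c_fragment,
    SimulationConfig, simulate_msms, preprocess,
    spacer_coverage, score_substitutions,
)

x = reference_sequence("gRNA X")
xb = reference_sequence("gRNA XB")       # 11 G>A spacer variant

print(f"{elemental_composition(x).average_mass:.2f}")   # 33148.39
print(f"{c_fragment(reference_sequence('gRNA XA'), 2).mz(1):.4f}")  # 670.0449

# simulate a 10 % variant spike and rediscover it
cfg = SimulationConfig(components=((x, 0.9), (xb, 0.1)), seed=11)
spec = preprocess([simulate_msms(cfg)])
print(f"{spacer_coverage(spec, x).percent:.0f}")        # 100
top = score_substitutions(spec, x)[0]
print(top.label, f"{top.score:.0f}")                    # 11 G>A 68097
```

The average mass is the intact neutral mass of the 100-mer from its
printed sequence; 670.0449 is the theoretical m/z of the singly
deprotonated c₂ ion of the position-2 variant; the last lines show a
simulated 10 % spike yielding full spacer coverage for the parent and
the planted `11 G>A` substitution ranked first by the discovery score.

A CLI mirrors the library (`spacerms mass|fragments|simulate|match|fdr|
discover|cufit|denovo|qc`), e.g.:

```sh
spacerms simulate "gRNA X" --seed 3 -o spec.tsv
spacerms qc spec.tsv "gRNA X"
```

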