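# Methods

## Sequence and mass model

Guides are modeled as ordered modified ribonucleotides, position 1 at
the 5′ end, with two orthogonal flags per position: 2′-O-methylation of
the ribose (`N(m)`, +CH₂ on the nucleoside) and a phosphorothioate on
the 3′ linkage (`N(ms)`; in this chemistry vocabulary the thioate
always rides on a 2′-O-methyl nucleotide, so `(ms)` implies both). A
trailing `(ms)` is rejected at parse: the flag describes a linkage and
the last nucleotide has none. Both termini are hydroxyl, the synthetic
sgRNA convention; this choice is validated by the bundled reference
guides, whose computed average masses agree with their certificate
values to ≤ 0.01 Da.

The intact composition is Σ nucleosides + one linkage acid per bond −
2 H₂O per bond, where the linkage acid is phosphoric acid H₃PO₄ or, for
a thioate, thiophosphoric acid H₃PO₃S.

Two mass tables are kept deliberately distinct:

* monoisotopic masses use current CODATA/AME exact isotope masses;
* average masses use the **1995 IUPAC standard atomic weights**
  (C 12.011, H 1.00794, N 14.0067, O 15.9994, P 30.973762, S 32.066).
  This is the table behind the mass calculators common in
  oligonucleotide QC; the newer abridged weights shift a 100-mer RNA by
  ≈ −0.1 Da, outside certificate agreement.

## Fragments

c_n = first n nucleosides + n linkage acids − 2n H₂O (the cleavage-site
(thio)phosphate stays on the 5′ fragment); y_n = last n nucleosides +
(n−1) linkage acids − 2(n−1) H₂O. Compositions of c_n and y_{N−n} sum
exactly to the parent — an invariant the tests enforce element-wise.
Negative-mode m/z is (M − z·1.007276)/z. With these definitions the
doubly modified c₂ of the bundled position-2 variant computes to
670.0449 at 1−, within 0.001 of the instrument-software value of
670.0444; the residual ~0.0005 likely reflects a slightly different
proton/electron bookkeeping in vendor software and is left unresolved.

## Isotope patterns

Isotopologues are aggregated by nucleon count (unit-mass bins). Each
element's single-atom distribution over extra neutrons is convolved by
binary exponentiation, carrying the probability vector together with
its first mass moment so each bin's centroid is the exact
abundance-weighted mean mass. Unpruned probabilities sum to 1 (tested
to 1e−6); peaks below 1e−4 of the maximum are pruned and patterns
max-normalized. Fine structure inside a bin is far below the 0.01 m/z
matching tolerance of QTOF data, so nothing finer is modeled, and no
averagine-style approximation is ever needed because compositions are
always known exactly.

Mixtures of two same-charge patterns are formed on a shared grid of
0.2/z-wide bins (well under half the 1.0034/z isotopologue spacing):
abundances combine as (1−f)·a + f·b and the result is renormalized.

The C↔U constants emerge from the composition difference (U−C = O−NH):
+0.984 Da between the monoisotopic forms, and the C form's first ¹³C
isotopologue 0.019 Da above the U monoisotopic — the interference that
motivates the dedicated mixture fit below.

## Spectrum preprocessing

Scans are averaged (point-wise for profile data on a shared axis; by
pooling peaks within 0.005 m/z — half the matching tolerance — for
centroided data), profile data are centroided by local-maximum
detection with an intensity-weighted centroid over contiguous
above-baseline points, then peaks with intensity < 500 counts and
peaks above 1310 m/z (precursor-dominated region) are removed. The
vendor centroiding used to produce real averaged spectra is not public;
the implementation here is documented as replaceable and preprocessing
is idempotent on already-centroided, filtered input.

## The simulator

The synthetic-spectrum generator emulates an averaged negative-mode
QTOF MS/MS acquisition of a guide mixture; it is the test bed for every
downstream stage. For each component (sequence, molar fraction), each
requested c/y fragment and charge state receives its full theoretical
envelope scaled by

    base_intensity · fraction · exp(−k·(n−1)) · w(z|n),

with base_intensity 1e6 counts, decay k = ln(20)/18 so that c₂₀
responds at ~5 % of c₂ (the empirically observed size ordering), and a
Gaussian charge preference w centred at 1 + (n−1)/3.5 with σ = 1.25.
Against the 500-count floor these defaults make a 1 % single-base
variant detectable on c₂–c₁₀ but not on c₁₅–c₂₀, where 5 % is required
— the sensitivity profile of real spike-in experiments. Peak positions
are jittered by N(0, 0.003 m/z) (instrument accuracy), intensities by
lognormal scatter (CV 2 %), and noise peaks are drawn uniformly in m/z
with exponential intensities around the floor. All randomness flows
from one seed; identical configurations are byte-identical.

What the simulator does *not* model: chromatography and elution
averaging artifacts, charge-state correlation between fragments,
secondary fragmentation, detector saturation, golden-pair suppression,
and real spectral congestion statistics. Tests passing on simulated
spectra therefore demonstrate algorithmic correctness under the stated
response model, not instrument-level performance.

## Matching and decoy FDR

A fragment is assigned when every isotopologue's nearest peak lies
within 0.01 m/z (ties broken toward the more intense peak), at least 2
adjacent isotopologues are matched, and the cosine between theoretical
and observed abundance vectors exceeds 0.80. Fragment abundance is the
observed intensity at the most abundant theoretical isotopologue; the
mass error is recorded at the most intense matched one. A peak may
serve two overlapping fragments — overlap lowers the cosine rather than
forbidding reuse.

FDR is estimated by shifting all theoretical m/z by each nonzero
multiple of 50 ppm within ±1000 ppm (40 decoy searches): FDR =
mean(random hits)/target hits. On noiseless simulations the
thresholded FDR is small but not zero (~3–4 %): an offset near
(1.0034/z)/mz realigns a decoy envelope one isotopologue over, and the
flattest (largest) envelopes survive the cosine cutoff. That residual
is intrinsic to the decoy construction, matching the few-percent floor
the method shows on real data.

## Substitution discovery and quantitation

Discovery enumerates all n×3 single-base permutations of the spacer
(C↔U pairs excluded — see below) and scores each by

    score = coverage² · Σ (abundance · cosine²)

summed over matches to the candidate-specific fragments c_n..c_m (n the
substitution site, m the spacer end), coverage being the matched
fraction of that range. The per-substitution-type maximum is the
headline view, since isomeric positions share fragment masses.

Per-site quantitation reports 100·A_variant/(A_variant+A_parent) with
abundances summed over all matched charge states (maximizing signal;
the choice of summing rather than selecting one charge state is a
package decision). Positions where the two forms are isobaric are
flagged indistinguishable rather than reported.

## C↔U mixture fitting

For C↔U substitutions the overlapping envelopes are deconvolved in two
stages: non-negative least squares of the observed envelope on the two
theoretical patterns (binned to the shared 0.2/z grid) seeds the
substitute fraction, which is then refined by bounded scalar
minimization of the cosine distance; the better of seed and refinement
is kept. Noiseless recovery is exact to < 0.01 over the tested range
f ∈ {0, 0.01, 0.05, 0.1, 0.5}.

The spacer-wide profile fits every c_n against its one-swap substitute
in both directions. Per position the reported fraction comes from the
charge state with the **best fit cosine** (per-charge fits below 0.80
are discarded; estimates with fit cosine < 0.95 are flagged
low-confidence). Averaging across charges was rejected: congestion
from a co-occurring fragment can shift one charge state's fitted
fraction by tens of points while barely denting its cosine, and the
best-fitting charge state proved the reliable one.

## De novo sequencing

Spacer mode extends partial sequences 5′→3′, keeping an extension only
if the c_k fragment of the extended prefix matches at some charge.
When C or U is called, the observed envelope is refitted as a C/U
mixture: a form carrying ≥ 5 % of the envelope spawns its branch, so
genuine mixtures propagate as two sequences while one-isotopologue
aliasing of the wrong form is pruned. At lengths 5, 10, 15, 20 (and
the final length) candidates are scored and each set of equal-mass
prefixes is reduced to its best coverage-weighted scorer (ties broken
lexicographically), suppressing scrambles; a beam cap of 512 bounds the
frontier. Impurity-tag mode allows ⌊tag_len/5⌋ missed fragments, never
within the first three positions (the most abundant fragments, whose
absence is disqualifying); candidates' final scores are weighted by
squared coverage.

Modification mode inverts the unknowns: bases known, per-position flag
state in {plain, methyl, methyl+thioate} searched out to position 28,
with complete coverage required over 1..20 and at most 2 missed
cleavages beyond (c-ion coverage past ~28 is too sparse to localize).
When a flanking fragment is missing, equally scored placements that
differ only across the gap are merged and reported as a position
stretch (e.g. methyl within 21–22) rather than a guessed single site.

## Problem sizes and defaults

Validation runs use the six bundled 100-mer references, spacer searches
c₁–c₂₀ at 1−..7−, full-sequence searches c/y₁–₉₉ at 1−..25−, and
modification searches to position 28 at 1−..12−. The spike-in
linearity study simulates the position-2 variant at 1/5/10/50 % molar
fraction and regresses measured against actual percentage per tracked
fragment (c₂, c₅, c₁₀, c₁₅, c₂₀); its R² is the mean over fragments.
These sizes run the whole suite in well under a minute of simulation
time while exercising every stage at full sequence scale.

## Known limitations

* Only 2′-O-methyl and phosphorothioate chemistry; no DNA/LNA bases or
  base methylations (isomeric with ribose methylation and
  indistinguishable at unit resolution anyway).
* No charge deconvolution/deisotoping: matching operates directly in
  centroided m/z space.
* y-ion-based 3′ de novo and simultaneous multi-site substitution
  fitting are not implemented.
* Decoy FDR inherits the isotopologue-aliasing floor described above.
* The simulator's response model is phenomenological; quantitative
  claims about real instruments require real spike-in calibration.
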