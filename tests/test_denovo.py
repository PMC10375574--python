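"""De novo spacer sequencing, impurity tags, and modification placement."""

import itertools

import numpy as np
import pytest

from spacerms import reference_sequence
from spacerms.fragments import FragmentSpecies, c_prefix_composition
from spacerms.denovo import (
    Scaffold,
    denovo_impurity_tags,
    denovo_modifications,
    denovo_spacer,
    summarize_placements,
)
from spacerms.matching import match_fragment
from spacerms.oligo import Nucleotide, OligoSequence, parse_sequence
from spacerms.spectra import Spectrum

from conftest import simulate

ALL_NAMES = ("gRNA X", "gRNA XA", "gRNA XB", "gRNA XC", "gRNA XD", "gRNA Y")


def spacer_bases(oligo):
    return "".join(nt.base for nt in oligo.spacer())


class TestSpacerDenovo:
    @pytest.mark.parametrize("name", ALL_NAMES)
    def test_true_spacer_ranks_first_on_noiseless_ladder(self, name):
        oligo = reference_sequence(name)
        spec = simulate([(oligo, 1.0)], seed=sum(map(ord, name)), noiseless=True)
        cands = denovo_spacer(spec, Scaffold.from_oligo(oligo))
        assert cands, f"no candidates for {name}"
        assert cands[0].bases == spacer_bases(oligo)
        assert cands[0].coverage == 1.0

    def test_noisy_spectrum_still_tops_truth(self, pure_x_noisy, grna_x):
        cands = denovo_spacer(pure_x_noisy, Scaffold.from_oligo(grna_x))
        assert cands[0].bases == spacer_bases(grna_x)

    def test_empty_spectrum_yields_nothing(self, grna_x):
        empty = Spectrum(np.array([]), np.array([]))
        assert denovo_spacer(empty, Scaffold.from_oligo(grna_x)) == []

    def test_weighted_score_is_score_times_coverage_squared(self, grna_x):
        spec = simulate([(grna_x, 1.0)], seed=37)
        for cand in denovo_spacer(spec, Scaffold.from_oligo(grna_x)):
            assert cand.weighted_score == pytest.approx(
                cand.score * cand.coverage**2
            )


class TestBruteForceOracle:
    """On a tiny instance the checkpointed search must agree with
    exhaustive enumeration over all sequences."""

    def test_matches_exhaustive_search(self):
        parent = parse_sequence("AGGAGA" + "U", name="toy")  # 6 searched + tail
        spec = simulate([(parent, 1.0)], seed=41, noiseless=True,
                        index_range=(1, 6))
        scaffold = Scaffold(
            tuple(nt.ribose_methyl for nt in parent.nucleotides[:6]),
            tuple(nt.thio_linkage for nt in parent.nucleotides[:6]),
        )

        def exhaustive_best():
            best = None
            for combo in itertools.product("AG", repeat=6):
                score = 0.0
                complete = True
                nts = ()
                for k, base in enumerate(combo, start=1):
                    nts = nts + (scaffold.nucleotide(k, base),)
                    frag = FragmentSpecies("bf", "c", k, c_prefix_composition(nts))
                    hits = [
                        match_fragment(spec, frag, z) for z in range(1, 8)
                    ]
                    hits = [m for m in hits if m is not None]
                    if not hits:
                        complete = False
                        break
                    score += sum(m.abundance * m.cosine**2 for m in hits)
                if complete:
                    key = (score, "".join(combo))
                    if best is None or score > best[0]:
                        best = key
            return best

        best = exhaustive_best()
        cands = denovo_spacer(spec, scaffold, max_len=6)
        assert best is not None and cands
        assert cands[0].bases == best[1]
        assert cands[0].score == pytest.approx(best[0])


class TestImpurityTags:
    def test_both_spacers_found_in_even_mixture(self, grna_x, grna_y):
        spec = simulate([(grna_x, 0.5), (grna_y, 0.5)], seed=9)
        tags = denovo_impurity_tags(spec, Scaffold.from_oligo(grna_x), 20)
        bases = {c.bases for c in tags}
        assert spacer_bases(grna_x) in bases
        assert spacer_bases(grna_y) in bases

    def test_five_percent_impurity_short_tag(self, grna_x, grna_y):
        spec = simulate([(grna_x, 0.95), (grna_y, 0.05)], seed=13)
        tags = denovo_impurity_tags(spec, Scaffold.from_oligo(grna_x), 5)
        assert spacer_bases(grna_y)[:5] in {c.bases for c in tags}

    def test_missing_c1_kills_all_candidates(self, grna_x):
        spec = simulate([(grna_x, 1.0)], seed=43, noiseless=True,
                        skip_indices=(1,))
        assert denovo_impurity_tags(spec, Scaffold.from_oligo(grna_x), 5) == []

    def test_tag_scores_scale_with_impurity_fraction(self, grna_x):
        """The raw (pre-coverage) tag score of a planted impurity whose
        fragments share no mass with the parent grows about linearly
        with its molar fraction."""
        impurity = parse_sequence("A(ms)A(ms)A(ms)GAGAGG", name="dissimilar")
        scores = []
        fractions = (0.05, 0.10, 0.20, 0.50)
        for i, frac in enumerate(fractions):
            spec = simulate([(grna_x, 1 - frac), (impurity, frac)], seed=47 + i)
            tags = denovo_impurity_tags(spec, Scaffold.from_oligo(impurity, 5), 5)
            by_bases = {c.bases: c.score for c in tags}
            scores.append(by_bases.get("AAAGA", 0.0))
        assert all(s > 0 for s in scores)
        x = np.array(fractions)
        y = np.array(scores)
        slope, intercept = np.polyfit(x, y, 1)
        pred = slope * x + intercept
        r2 = 1 - np.sum((y - pred) ** 2) / np.sum((y - y.mean()) ** 2)
        assert r2 > 0.95

    def test_invalid_tag_length_rejected(self, pure_x_noisy, grna_x):
        with pytest.raises(ValueError):
            denovo_impurity_tags(pure_x_noisy, Scaffold.from_oligo(grna_x), 7)


class TestModificationPlacement:
    CHARGES = tuple(range(1, 13))

    def _spectrum(self, oligo, seed, **kw):
        return simulate([(oligo, 1.0)], seed=seed, index_range=(1, 28),
                        charges=self.CHARGES, **kw)

    def test_full_coverage_recovers_all_sites(self, grna_xa):
        spec = self._spectrum(grna_xa, seed=2)
        mods = denovo_modifications(
            spec, "".join(nt.base for nt in grna_xa.nucleotides[:28]),
            charges=self.CHARGES,
        )
        top = mods[0]
        assert sorted(top.methyl_positions) == [1, 2, 3, 21, 28]
        assert sorted(top.thio_positions) == [1, 2, 3]
        assert top.missed == ()

    def test_missing_flank_reported_as_stretch(self, grna_xa):
        """With c21 absent the position-21 methyl is only localizable to
        the 21-22 stretch."""
        spec = self._spectrum(grna_xa, seed=2, skip_indices=(21,))
        mods = denovo_modifications(
            spec, "".join(nt.base for nt in grna_xa.nucleotides[:28]),
            charges=self.CHARGES,
        )
        summary = summarize_placements(mods)
        assert summary["methyl"] >= {1, 2, 3, 28}
        assert (21, 22) in summary["methyl_stretches"]
        assert summary["thio"] == {1, 2, 3}

    def test_unmodified_sequence_gets_no_flags(self):
        plain = parse_sequence("CAGGUUCCAUGGGAUGCUCUGUUUUAGAG", name="plain")
        spec = simulate([(plain, 1.0)], seed=53, index_range=(1, 28),
                        charges=self.CHARGES, noiseless=True)
        mods = denovo_modifications(
            spec, "CAGGUUCCAUGGGAUGCUCUGUUUUAGA", charges=self.CHARGES,
        )
        top = mods[0]
        assert top.methyl_positions == frozenset()
        assert top.thio_positions == frozenset()
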