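"""Substitution discovery scoring, site quantitation, and C/U mixture fits."""

import numpy as np
import pytest

from spacerms.fragments import c_fragment
from spacerms.impurity import (
    cu_profile,
    cu_substitute_composition,
    fit_cu_mixture,
    linearity_r2,
    max_score_by_type,
    mean_cu_percent,
    quantify_variant_sites,
    score_substitutions,
    spike_in_series,
)
from spacerms.isotopes import isotope_distribution, mixture_distribution

from conftest import simulate


class TestDiscoveryScore:
    def test_score_formula_recomputes_from_matches(self, grna_x):
        """Candidate score equals coverage^2 * sum(abundance * cosine^2)
        over its returned unique-fragment matches."""
        spec = simulate([(grna_x, 1.0)], seed=31)
        cands = score_substitutions(spec, grna_x)
        checked = 0
        for c in cands:
            if not c.matches:
                continue
            total = sum(m.abundance * m.cosine**2 for m in c.matches)
            assert c.score == pytest.approx(c.coverage**2 * total)
            checked += 1
        assert checked > 0

    def test_score_monotone_in_abundance(self):
        """Doubling a matched fragment's abundance never lowers the score."""
        base = 0.8**2 * (1000.0 + 500.0)
        boosted = 0.8**2 * (2000.0 + 500.0)
        assert boosted > base  # direct consequence of the additive form

    def test_planted_gb_substitution_ranks_first(self, grna_x, grna_xb):
        spec = simulate([(grna_x, 0.9), (grna_xb, 0.1)], seed=11)
        cands = score_substitutions(spec, grna_x)
        assert cands[0].label == "11 G>A"
        by_type = max_score_by_type(cands)
        top_type = max(by_type, key=by_type.get)
        assert top_type == ("G", "A")

    def test_exclude_cu_drops_cu_candidates(self, pure_x_noisy, grna_x):
        cands = score_substitutions(pure_x_noisy, grna_x, exclude_cu=True)
        assert all({c.from_base, c.to_base} != {"C", "U"} for c in cands)
        assert len(cands) == 49


class TestQuantifySites:
    def test_fifty_fifty_recovered(self, grna_x, grna_xa):
        spec = simulate([(grna_x, 0.5), (grna_xa, 0.5)], seed=17,
                        noiseless=True)
        sites = quantify_variant_sites(spec, grna_x, grna_xa, [2, 5, 10])
        for s in sites:
            assert s.flag == "ok"
            assert s.percent == pytest.approx(50.0, abs=1.0)

    def test_shared_mass_position_flagged(self, pure_x_noisy, grna_x, grna_xb):
        """The 11 G>A variant's c5 has the parent's mass: indistinguishable."""
        sites = quantify_variant_sites(pure_x_noisy, grna_x, grna_xb, [5, 11])
        by_pos = {s.position: s for s in sites}
        assert by_pos[5].flag == "indistinguishable"
        assert by_pos[11].flag == "ok"

    def test_zero_spike_measures_zero(self, pure_x_clean, grna_x, grna_xa):
        sites = quantify_variant_sites(pure_x_clean, grna_x, grna_xa,
                                       [2, 5, 10, 15, 20])
        for s in sites:
            assert s.flag in ("ok", "undefined")
            if s.flag == "ok":
                assert s.percent == pytest.approx(0.0, abs=0.5)

    def test_noiseless_recovery_within_one_point(self, grna_x, grna_xa):
        spec = simulate([(grna_x, 0.9), (grna_xa, 0.1)], seed=23,
                        noiseless=True)
        for s in quantify_variant_sites(spec, grna_x, grna_xa, [2, 5, 10, 15, 20]):
            assert s.percent == pytest.approx(10.0, abs=1.0)

    def test_noisy_recovery_small_fractions(self, grna_x, grna_xa):
        """With the default noise model, fractions >= 1 % recover within
        2 points at the 5'-proximal positions."""
        for frac in (0.01, 0.05):
            spec = simulate([(grna_x, 1 - frac), (grna_xa, frac)], seed=29)
            for s in quantify_variant_sites(spec, grna_x, grna_xa, [2, 5, 10]):
                assert s.flag == "ok"
                assert s.percent == pytest.approx(100 * frac, abs=2.0)


class TestSpikeInLinearity:
    def test_r2_above_099(self, grna_x, grna_xa):
        table = spike_in_series(
            grna_x, grna_xa, [0.01, 0.05, 0.10, 0.50], [2, 5, 10, 15, 20],
            seed=42,
        )
        r2 = linearity_r2(table)
        assert set(r2) == {2, 5, 10, 15, 20}
        assert np.mean(list(r2.values())) >= 0.99


class TestCuMixtureFit:
    @pytest.mark.parametrize("f_true", [0.0, 0.01, 0.05, 0.1, 0.5])
    def test_recovery_on_noiseless_mixtures(self, grna_x, grna_xd, f_true):
        parent = c_fragment(grna_x, 5).composition
        substitute = c_fragment(grna_xd, 5).composition
        observed = mixture_distribution(
            isotope_distribution(parent, 2),
            isotope_distribution(substitute, 2),
            f_true,
        )
        fit = fit_cu_mixture(observed, parent, substitute)
        assert abs(fit.fraction_substitute - f_true) <= 0.02
        assert fit.cosine > 0.999

    def test_pure_parent_fits_zero(self, grna_x):
        parent = c_fragment(grna_x, 5).composition
        substitute = cu_substitute_composition(parent, "u_to_c")
        observed = isotope_distribution(parent, 2)
        fit = fit_cu_mixture(observed, parent, substitute)
        assert fit.fraction_substitute == pytest.approx(0.0, abs=0.01)

    def test_degenerate_design_rejected(self, grna_x):
        parent = c_fragment(grna_x, 5).composition
        observed = isotope_distribution(parent, 2)
        with pytest.raises(ValueError):
            fit_cu_mixture(observed, parent, parent)


class TestCuProfile:
    def test_plateau_from_substitution_site(self, grna_x, grna_xd):
        """50 % of the U>C-at-5 variant: no signal before position 5,
        ~50 % substitute from position 5 to the spacer end."""
        spec = simulate([(grna_x, 0.5), (grna_xd, 0.5)], seed=3)
        prof = cu_profile(spec, grna_x)["u_to_c"]
        assert all(n >= 5 for n in prof)  # positions 1-4 have no U
        assert mean_cu_percent(prof, 5, 20) == pytest.approx(50.0, abs=5.0)

    def test_no_spike_noiseless_near_zero(self, pure_x_clean, grna_x):
        prof = cu_profile(pure_x_clean, grna_x)
        for direction in ("u_to_c", "c_to_u"):
            for est in prof[direction].values():
                assert est.percent == pytest.approx(0.0, abs=2.0)

    def test_inverse_direction_detected(self, grna_x, grna_xd):
        """X spiked into XD appears as a C>U substitute rising at 5."""
        spec = simulate([(grna_xd, 0.5), (grna_x, 0.5)], seed=19)
        prof = cu_profile(spec, grna_xd)["c_to_u"]
        assert mean_cu_percent(prof, 5, 20) == pytest.approx(50.0, abs=5.0)
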