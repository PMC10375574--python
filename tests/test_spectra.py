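"""Spectrum I/O, preprocessing rules, and simulator behavior."""

import numpy as np
import pytest

from spacerms.spectra import (
    SimulationConfig,
    Spectrum,
    SpectrumFormatError,
    centroid,
    clean_config,
    load_spectra,
    preprocess,
    simulate_msms,
    write_tsv,
)


class TestTsvIO:
    def test_round_trip(self, tmp_path, grna_x):
        spec = simulate_msms(clean_config([(grna_x, 1.0)], seed=3))
        path = tmp_path / "spec.tsv"
        write_tsv(spec, path)
        (loaded,) = load_spectra(path)
        assert np.allclose(loaded.mz, spec.mz, atol=1e-6)
        assert np.allclose(loaded.intensity, spec.intensity, atol=1e-6)

    def test_two_scan_blocks(self, tmp_path):
        path = tmp_path / "two.tsv"
        path.write_text("100.0\t10\n101.0\t20\n\n200.0\t5\n")
        scans = load_spectra(path)
        assert len(scans) == 2
        assert len(scans[0]) == 2 and len(scans[1]) == 1

    def test_empty_file_rejected(self, tmp_path):
        path = tmp_path / "empty.tsv"
        path.write_text("")
        with pytest.raises(SpectrumFormatError):
            load_spectra(path)

    def test_malformed_line_names_record(self, tmp_path):
        path = tmp_path / "bad.tsv"
        path.write_text("100.0\t10\nnot-a-peak\n")
        with pytest.raises(SpectrumFormatError, match="bad.tsv:2"):
            load_spectra(path)


def _write_mzml(path, scans, compress_intensity=False):
    """Minimal mzML writer for round-trip tests (64-bit, optional zlib)."""
    import base64
    import zlib

    def encode(arr, compress):
        raw = np.asarray(arr, dtype="<f8").tobytes()
        if compress:
            raw = zlib.compress(raw)
        return base64.b64encode(raw).decode()

    comp_cv = (
        '<cvParam cvRef="MS" accession="MS:1000574" name="zlib compression"/>'
    )
    nocomp_cv = (
        '<cvParam cvRef="MS" accession="MS:1000576" name="no compression"/>'
    )
    blocks = []
    for i, (mz, inten) in enumerate(scans):
        blocks.append(f"""
      <spectrum index="{i}" id="scan={i + 1}" defaultArrayLength="{len(mz)}">
        <cvParam cvRef="MS" accession="MS:1000127" name="centroid spectrum"/>
        <binaryDataArrayList count="2">
          <binaryDataArray>
            <cvParam cvRef="MS" accession="MS:1000523" name="64-bit float"/>
            {nocomp_cv}
            <cvParam cvRef="MS" accession="MS:1000514" name="m/z array"/>
            <binary>{encode(mz, False)}</binary>
          </binaryDataArray>
          <binaryDataArray>
            <cvParam cvRef="MS" accession="MS:1000523" name="64-bit float"/>
            {comp_cv if compress_intensity else nocomp_cv}
            <cvParam cvRef="MS" accession="MS:1000515" name="intensity array"/>
            <binary>{encode(inten, compress_intensity)}</binary>
          </binaryDataArray>
        </binaryDataArrayList>
      </spectrum>""")
    path.write_text(
        '<?xml version="1.0" encoding="utf-8"?>\n'
        '<mzML xmlns="http://psi.hupo.org/ms/mzml" version="1.1.0">\n'
        f'  <run id="r"><spectrumList count="{len(scans)}">{"".join(blocks)}\n'
        "  </spectrumList></run>\n</mzML>\n"
    )


class TestMzmlIO:
    def test_round_trip_two_scans(self, tmp_path):
        scans = [
            ([100.0, 200.5, 300.25], [10.0, 20.0, 30.0]),
            ([150.0], [5.0]),
        ]
        path = tmp_path / "tiny.mzML"
        _write_mzml(path, scans, compress_intensity=True)
        loaded = load_spectra(path)
        assert len(loaded) == 2
        assert loaded[0].mode == "centroid"
        assert np.allclose(loaded[0].mz, scans[0][0])
        assert np.allclose(loaded[0].intensity, scans[0][1])
        assert np.allclose(loaded[1].mz, scans[1][0])

    def test_malformed_mzml_rejected(self, tmp_path):
        path = tmp_path / "broken.mzML"
        path.write_text("<mzML><spectrum></mzML>")
        with pytest.raises(SpectrumFormatError):
            load_spectra(path)


class TestPreprocess:
    def test_noise_floor_rule(self):
        spec = Spectrum(np.array([500.0, 600.0]), np.array([499.0, 501.0]))
        out = preprocess([spec])
        assert out.mz.tolist() == [600.0]

    def test_high_mz_cutoff(self):
        spec = Spectrum(np.array([1309.9, 1310.1]), np.array([1e4, 1e6]))
        out = preprocess([spec])
        assert out.mz.tolist() == [1309.9]

    def test_empty_result_is_not_an_error(self):
        spec = Spectrum(np.array([100.0]), np.array([1.0]))
        out = preprocess([spec])
        assert len(out) == 0

    def test_empty_scan_list_rejected(self):
        with pytest.raises(ValueError):
            preprocess([])

    def test_idempotent_on_filtered_centroided(self, pure_x_noisy):
        again = preprocess([pure_x_noisy])
        assert np.array_equal(again.mz, pure_x_noisy.mz)
        assert np.array_equal(again.intensity, pure_x_noisy.intensity)

    def test_profile_centroiding_weighted_centroid(self):
        mz = np.array([99.98, 100.0, 100.02, 100.04, 200.0])
        inten = np.array([500.0, 1000.0, 500.0, 0.0, 800.0])
        spec = Spectrum(mz, inten, mode="profile")
        out = centroid(spec)
        assert len(out) == 2
        assert out.mz[0] == pytest.approx(100.0, abs=1e-6)


class TestSimulator:
    def test_deterministic_under_seed(self, grna_x):
        cfg = SimulationConfig(((grna_x, 1.0),), seed=5)
        a, b = simulate_msms(cfg), simulate_msms(cfg)
        assert np.array_equal(a.mz, b.mz)
        assert np.array_equal(a.intensity, b.intensity)

    def test_fractions_must_sum_to_one(self, grna_x, grna_xa):
        cfg = SimulationConfig(((grna_x, 0.9), (grna_xa, 0.2)), seed=0)
        with pytest.raises(ValueError):
            simulate_msms(cfg)

    def test_full_ladder_recoverable(self, pure_x_clean, grna_x):
        from spacerms.matching import spacer_coverage

        assert spacer_coverage(pure_x_clean, grna_x).percent == 100.0

    def test_one_percent_variant_c2_above_floor(self, grna_x, grna_xa):
        """A 1 % single-substitution spike leaves its c2 monoisotopic
        peak above the 500-count noise floor."""
        from spacerms.fragments import c_fragment
        from spacerms.matching import match_fragment

        cfg = SimulationConfig(((grna_x, 0.99), (grna_xa, 0.01)), seed=21)
        spec = preprocess([simulate_msms(cfg)])
        m = match_fragment(spec, c_fragment(grna_xa, 2), 1)
        assert m is not None and m.abundance >= 500.0

    def test_component_ratio_converges_without_noise(self, grna_x, grna_xa):
        from spacerms.fragments import c_fragment
        from spacerms.matching import match_fragment

        cfg = clean_config([(grna_x, 0.8), (grna_xa, 0.2)], seed=2)
        spec = preprocess([simulate_msms(cfg)], noise_floor=0.0)
        a_p = match_fragment(spec, c_fragment(grna_x, 5), 2).abundance
        a_v = match_fragment(spec, c_fragment(grna_xa, 5), 2).abundance
        assert a_v / (a_p + a_v) == pytest.approx(0.2, abs=0.01)
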