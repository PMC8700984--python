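import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from conchicore.proteome_match import (
    PROTON,
    WATER,
    PeptideIndex,
    Psm,
    Spectrum,
    build_peptide_index,
    digest_tryptic,
    fragment_ions,
    infer_smps,
    match_spectrum,
    peptide_mono_mass,
    read_mgf,
    write_mgf,
)
from oracles import oracle_digest

aa_seq = st.text(alphabet="ACDEFGHIKLMNPQRSTVWY", min_size=1, max_size=40)


def ladder_spectrum(sequence, spec_id="s", charge=2, keep=None):
    """Noise-free spectrum holding the b/y ladder (or a chosen subset)."""
    ions = fragment_ions(sequence)
    mz = np.array(sorted(m for k, (_, _, m) in enumerate(ions) if keep is None or k in keep))
    return Spectrum(
        spec_id,
        (peptide_mono_mass(sequence) + charge * PROTON) / charge,
        charge,
        mz,
        np.ones_like(mz),
    )


class TestDigestTryptic:
    def test_cleaves_after_k_and_r_but_not_before_proline(self):
        peps = digest_tryptic("AKRPGKR", max_missed_cleavages=0, min_len=None, max_len=None)
        assert [p.sequence for p in peps] == ["AK", "RPGK", "R"]
        assert "".join(p.sequence for p in peps) == "AKRPGKR"

    def test_one_missed_cleavage_adds_adjacent_fusions(self):
        peps = digest_tryptic("AKRPGKR", max_missed_cleavages=1, min_len=None, max_len=None)
        assert {p.sequence for p in peps if p.missed_cleavages == 1} == {"AKRPGK", "RPGKR"}

    def test_protein_without_cleavage_sites_is_one_peptide(self):
        peps = digest_tryptic("AGGAGA", max_missed_cleavages=2, min_len=None, max_len=None)
        assert [p.sequence for p in peps] == ["AGGAGA"]

    @settings(max_examples=100, derandomize=True)
    @given(aa_seq, st.integers(0, 3))
    def test_matches_brute_force_enumeration(self, protein, max_mc):
        got = {
            (p.sequence, p.start, p.missed_cleavages)
            for p in digest_tryptic(protein, max_missed_cleavages=max_mc,
                                    min_len=None, max_len=None)
        }
        assert got == oracle_digest(protein, max_mc)

    def test_length_bounds_match_oracle(self):
        rng = np.random.default_rng(1)
        aas = "ACDEFGHIKLMNPQRSTVWY"
        for _ in range(50):
            protein = "".join(rng.choice(list(aas), size=rng.integers(5, 41)))
            got = {
                (p.sequence, p.start, p.missed_cleavages)
                for p in digest_tryptic(protein, 2, min_len=3, max_len=12)
            }
            assert got == oracle_digest(protein, 2, min_len=3, max_len=12)


class TestMasses:
    def test_glycine_mass(self):
        assert peptide_mono_mass("G") == pytest.approx(75.03203, abs=1e-4)

    def test_peptide_mass_against_independent_table(self):
        assert peptide_mono_mass("PEPTIDE") == pytest.approx(799.3600, abs=1e-3)

    def test_cross_check_with_pyteomics(self):
        from pyteomics import mass

        for seq in ["PEPTIDE", "ACDEFGHIK", "WWWW", "KRPGK"]:
            assert peptide_mono_mass(seq) == pytest.approx(
                mass.fast_mass(seq), abs=1e-3
            )

    def test_concatenation_additivity(self):
        a, b = "ACDK", "MPR"
        assert peptide_mono_mass(a + b) == pytest.approx(
            peptide_mono_mass(a) + peptide_mono_mass(b) - WATER, abs=1e-9
        )

    def test_nonstandard_residue_errors(self):
        with pytest.raises(ValueError):
            peptide_mono_mass("AXC")


class TestFragmentIons:
    def test_two_residue_ladder(self):
        ions = {(t, i): mz for t, i, mz in fragment_ions("AG")}
        assert ions[("b", 1)] == pytest.approx(72.04439, abs=1e-4)
        assert ions[("y", 1)] == pytest.approx(76.03930, abs=1e-4)
        assert len(ions) == 2

    def test_by_complementarity_identity(self):
        seq = "PEPTIDEK"
        n = len(seq)
        ions = {(t, i): mz for t, i, mz in fragment_ions(seq)}
        neutral = peptide_mono_mass(seq)
        for i in range(1, n):
            assert ions[("b", i)] + ions[("y", n - i)] == pytest.approx(
                neutral + 2 * PROTON, abs=1e-9
            )


class TestMatchSpectrum:
    def test_self_match_scores_one(self):
        index = PeptideIndex(digest_tryptic("MPEPTIDEKACDEFGHIK", "p|+1|0-18"))
        psm = match_spectrum(ladder_spectrum("MPEPTIDEK"), index)
        assert psm is not None
        assert psm.peptide.sequence == "MPEPTIDEK"
        assert psm.score == 1.0

    def test_empty_spectrum_gives_no_match(self):
        index = PeptideIndex(digest_tryptic("MPEPTIDEKACDEFGHIK", "p|+1|0-18"))
        empty = ladder_spectrum("MPEPTIDEK", keep=set())
        assert match_spectrum(empty, index) is None

    def test_half_deleted_ladder_scores_half(self):
        seq = "MPEPTIDEK"
        n_ions = len(fragment_ions(seq))
        keep = set(range(0, n_ions, 2))
        index = PeptideIndex(digest_tryptic("MPEPTIDEKACDEFGHIK", "p|+1|0-18"))
        psm = match_spectrum(ladder_spectrum(seq, keep=keep), index)
        assert psm.score == pytest.approx(len(keep) / n_ions, abs=1e-9)

    def test_precursor_mass_gates_candidates(self):
        index = PeptideIndex(digest_tryptic("MPEPTIDEKACDEFGHIK", "p|+1|0-18"))
        spec = ladder_spectrum("MPEPTIDEK")
        spec.precursor_mz += 5.0  # far outside 10 ppm
        assert match_spectrum(spec, index) is None


class TestInferSmps:
    def _psm(self, orf_id, seq, spec_id, score=0.9):
        peps = [p for p in digest_tryptic(seq + "K", orf_id, min_len=None, max_len=None)]
        return Psm(spec_id, peps[0], score, 0.0)

    def test_two_distinct_peptides_single_frame_accepted(self):
        psms = [
            self._psm("c1|+1|0-200", "AAADDDE", "s1"),
            self._psm("c1|+1|0-200", "CCCDDDE", "s2"),
        ]
        (cand,) = infer_smps(psms)
        assert cand.status == "accepted_single_frame"
        assert cand.distinct_peptides == 2

    def test_repeated_peptide_is_counted_once(self):
        psms = [self._psm("c1|+1|0-200", "AAADDDE", f"s{i}") for i in range(3)]
        (cand,) = infer_smps(psms)
        assert cand.status == "rejected_insufficient_peptides"
        # spectrum-counting mode accepts the same evidence
        (cand2,) = infer_smps(psms, count_spectra=True)
        assert cand2.status == "accepted_single_frame"

    def test_two_frames_excluded(self):
        psms = [
            self._psm("c1|+1|0-200", "AAADDDE", "s1"),
            self._psm("c1|-2|3-150", "CCCDDDE", "s2"),
        ]
        (cand,) = infer_smps(psms)
        assert cand.status == "excluded_multi_frame"
        assert cand.frames == (-2, 1)

    def test_low_score_psms_do_not_trigger_multiframe(self):
        psms = [
            self._psm("c1|+1|0-200", "AAADDDE", "s1"),
            self._psm("c1|+1|0-200", "CCCDDDE", "s2"),
            self._psm("c1|-2|3-150", "WWWDDDE", "s3", score=0.1),
        ]
        (cand,) = infer_smps(psms, min_score=0.4)
        assert cand.status == "accepted_single_frame"


class TestMgfRoundtrip:
    def test_write_then_read_preserves_spectra(self, tmp_path):
        spectra = [ladder_spectrum("MPEPTIDEK", "alpha"), ladder_spectrum("ACDEFGHIK", "beta")]
        path = tmp_path / "spectra.mgf"
        write_mgf(spectra, path)
        back = read_mgf(path)
        assert [s.id for s in back] == ["alpha", "beta"]
        for orig, rt in zip(spectra, back):
            assert rt.precursor_charge == orig.precursor_charge
            assert rt.precursor_mz == pytest.approx(orig.precursor_mz, abs=1e-6)
            assert np.allclose(rt.peaks_mz, orig.peaks_mz)
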