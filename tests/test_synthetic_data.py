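import numpy as np
import pytest

from conchicore import pipeline
from conchicore.proteome_match import (
    PeptideIndex,
    build_peptide_index,
    digest_tryptic,
    infer_smps,
    match_spectrum,
)
from conchicore.synthetic_data import (
    FOCAL,
    SimConfig,
    back_translate,
    load_fixtures,
    simulate_all,
    simulate_species_sets,
)
from conchicore.transcript_orf import six_frame_translate


SMALL = dict(
    n_smp_proteins=8,
    n_decoy_contigs=5,
    core_structure={"shared_all": 1, "marine_only": 1, "pair_shared": 1},
    n_other_specific=2,
    spectra_per_smp=2,
)


class TestDeterminism:
    def test_same_seed_reproduces_identical_datasets(self):
        a = simulate_all(SimConfig(seed=7, **SMALL))
        b = simulate_all(SimConfig(seed=7, **SMALL))
        assert [c.sequence for c in a.contigs] == [c.sequence for c in b.contigs]
        assert a.species_sets == b.species_sets
        for sa, sb in zip(a.spectra, b.spectra):
            assert sa.id == sb.id
            assert np.array_equal(sa.peaks_mz, sb.peaks_mz)
            assert sa.precursor_mz == sb.precursor_mz

    def test_different_seeds_differ(self):
        a = simulate_all(SimConfig(seed=7, **SMALL))
        b = simulate_all(SimConfig(seed=8, **SMALL))
        assert [c.sequence for c in a.contigs] != [c.sequence for c in b.contigs]


class TestConfigValidation:
    def test_core_structure_must_fit(self):
        with pytest.raises(ValueError):
            SimConfig(n_smp_proteins=5, core_structure={"shared_all": 6, "marine_only": 0, "pair_shared": 0})

    def test_identity_must_exceed_random_expectation(self):
        with pytest.raises(ValueError):
            SimConfig(homolog_identity=0.04)


class TestBackTranslation:
    def test_round_trips_through_translation(self):
        rng = np.random.default_rng(3)
        from conchicore.transcript_orf import Contig

        protein = "MKAVLLTWCDEFGHIKLMNPQRSTVWY"
        cds = back_translate(protein, rng)
        frames = {f.frame: f.aa_sequence for f in six_frame_translate(Contig("c", cds))}
        assert frames[1] == protein


class TestPlantedStructureRecovery:
    def test_no_frameshifts_means_no_multiframe_exclusions(self):
        bundle = simulate_all(SimConfig(seed=5, frac_frameshift=0.0, **SMALL))
        _, _, _, cands = pipeline.run_proteogenomics(bundle)
        assert all(c.status != "excluded_multi_frame" for c in cands)

    def test_single_spectrum_proteins_are_rejected_by_the_two_peptide_rule(self):
        cfg = dict(SMALL, n_single_peptide_smps=2)
        bundle = simulate_all(SimConfig(seed=5, frac_frameshift=0.0, **cfg))
        _, _, _, cands = pipeline.run_proteogenomics(bundle)
        status = {c.contig_id: c.status for c in cands}
        assert sorted(bundle.truth.expected_rejected) == sorted(
            cid for cid, s in status.items() if s == "rejected_insufficient_peptides"
        )

    def test_noise_free_spectra_score_one(self):
        cfg = SimConfig(
            seed=5, frac_frameshift=0.0, fragment_dropout=0.0,
            noise_peak_rate=0.0, precursor_jitter_ppm=0.0, **SMALL
        )
        bundle = simulate_all(cfg)
        _, _, psms, _ = pipeline.run_proteogenomics(bundle)
        assert psms and all(p.score == 1.0 for p in psms)

    def test_count_bookkeeping_partitions_identified_contigs(self):
        bundle = simulate_all(SimConfig(seed=11, n_single_peptide_smps=3, **SMALL))
        _, _, _, cands = pipeline.run_proteogenomics(bundle)
        from collections import Counter

        counts = Counter(c.status for c in cands)
        assert sum(counts.values()) == len(cands)
        assert counts["accepted_single_frame"] + counts["excluded_multi_frame"] + counts[
            "rejected_insufficient_peptides"
        ] == len(cands)


class TestDecoyControl:
    def test_decoy_acceptance_is_monotone_in_score_threshold(self):
        config = SimConfig(
            seed=13, frac_frameshift=0.0, fragment_dropout=0.55,
            noise_peak_rate=0.5, **SMALL
        )
        species_sets, truth = simulate_species_sets(config)
        rng = np.random.default_rng(13)
        from conchicore.synthetic_data import _eligible_peptides, _render_spectrum

        proteins = {
            f"t{i}|+1|0-999": seq
            for i, seq in enumerate(species_sets[FOCAL].values())
        }
        decoys = {pid.replace("t", "decoy", 1): seq[::-1] for pid, seq in proteins.items()}
        index = build_peptide_index({**proteins, **decoys})
        spectra = []
        for pid, seq in proteins.items():
            for k, pep in enumerate(_eligible_peptides(seq)[:3]):
                spectra.append(_render_spectrum(pep, f"s|{pid}|{k}", config, rng))
        psms = [p for p in (match_spectrum(s, index) for s in spectra) if p]
        prev = None
        for thr in (0.0, 0.2, 0.4, 0.6, 0.8, 1.0):
            cands = infer_smps(psms, min_score=thr)
            n_decoy = sum(
                1 for c in cands
                if c.contig_id.startswith("decoy") and c.status == "accepted_single_frame"
            )
            if prev is not None:
                assert n_decoy <= prev
            prev = n_decoy
        assert prev == 0  # nothing survives at min_score = 1


class TestFixtures:
    def test_table1_has_47_rows_27_annotated(self):
        df = load_fixtures("table1")
        assert len(df) == 47
        assert (df["annotation"] != "None").sum() == 27
        assert (df["annotation"] == "None").sum() == 20

    def test_coreset_fixture_names_three_all_conchiferan_proteins(self):
        m = load_fixtures("coreset_proteins_setting2")
        all_true = [f for f in m.features if all(m.cell(f, s) for s in m.species)]
        assert sorted(all_true) == [
            "CD109 Antigen protein", "Pif/BMSP-like protein", "Tyrosinase"
        ]

    def test_species_tree_leaves(self):
        from conchicore.ancestral_phylo import read_newick

        tree = read_newick(load_fixtures("species_tree"))
        assert sorted(t.name for t in tree.tips()) == [
            "Crassostrea", "Euhadra", "Lottia", "Nautilus", "Pinctada"
        ]

    def test_checksum_tamper_detection(self, tmp_path, monkeypatch):
        import conchicore.synthetic_data as sd
        import json, hashlib

        real = sd._read_fixture("table1.tsv")
        monkeypatch.setattr(
            sd.hashlib, "sha256", lambda data: hashlib.md5(data)
        )
        with pytest.raises(ValueError, match="checksum"):
            sd._read_fixture("table1.tsv")
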