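"""End-to-end driver: simulate -> translate -> match -> compare -> ancestral.

Chains the stage modules into the full identification-and-comparison
analysis and scores the outcome against the generator's GroundTruth. Used
by the analysis scripts, the acceptance script and the recovery tests.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

from . import synthetic_data as sd
from .transcript_orf import assembly_stats, find_orfs, six_frame_translate
from .proteome_match import (
    Psm,
    build_peptide_index,
    infer_smps,
    match_spectrum,
)
from .homology_coresets import (
    SETTING2,
    CoreSets,
    PresenceMatrix,
    SearchSetting,
    core_sets,
    reciprocal_search,
)
from .domain_annotation import (
    annotate_species_domains,
    domain_presence_matrix,
    load_profiles,
)
from .ancestral_phylo import dollo_ancestral, load_species_tree


@dataclass
class PipelineResult:
    bundle: sd.SimBundle
    stats: object
    candidates: list
    psms: list
    accepted_contigs: list
    excluded_contigs: list
    rejected_contigs: list
    focal_orf_sequences: dict  # protein id -> ORF-derived sequence
    protein_matrix: PresenceMatrix
    protein_coresets: CoreSets
    domain_matrix: PresenceMatrix
    domain_coresets: CoreSets
    ancestral: object
    recovery: dict


def run_proteogenomics(bundle: sd.SimBundle, min_orf_len: int = 100, min_score: float = 0.4):
    """Translate contigs, match spectra, and infer SMP candidates."""
    frames = [f for c in bundle.contigs for f in six_frame_translate(c)]
    orfs = find_orfs(frames, min_orf_len=min_orf_len)
    orf_seqs = {o.id: o.aa_sequence for o in orfs}
    index = build_peptide_index(orf_seqs)
    psms = []
    for spectrum in bundle.spectra:
        psm = match_spectrum(spectrum, index)
        if psm is not None:
            psms.append(psm)
    candidates = infer_smps(psms, min_score=min_score)
    return orfs, orf_seqs, psms, candidates


def run_end_to_end(
    config: Optional[sd.SimConfig] = None,
    setting: SearchSetting = SETTING2,
    min_orf_len: int = 100,
    min_score: float = 0.4,
) -> PipelineResult:
    """The full analysis on one simulated dataset, scored against GroundTruth."""
    bundle = sd.simulate_all(config)
    truth = bundle.truth
    stats = assembly_stats(bundle.contigs)
    orfs, orf_seqs, psms, candidates = run_proteogenomics(bundle, min_orf_len, min_score)

    accepted = sorted(c.contig_id for c in candidates if c.status == "accepted_single_frame")
    excluded = sorted(c.contig_id for c in candidates if c.status == "excluded_multi_frame")
    rejected = sorted(c.contig_id for c in candidates if c.status == "rejected_insufficient_peptides")

    # the supporting ORF sequence of each accepted contig, keyed by the
    # planted protein id so classifications can be scored against truth
    psms_by_contig: dict[str, list[Psm]] = {}
    for p in psms:
        cid = p.peptide.parent_protein_id.rsplit("|", 2)[0]
        psms_by_contig.setdefault(cid, []).append(p)
    focal_orf_sequences = {}
    for cid in accepted:
        orf_ids = [p.peptide.parent_protein_id for p in psms_by_contig[cid]]
        orf_id = max(set(orf_ids), key=orf_ids.count)
        focal_orf_sequences[truth.contigs[cid]["protein_id"]] = orf_seqs[orf_id]

    other_sets = {
        sp: prots for sp, prots in bundle.species_sets.items() if sp != sd.FOCAL
    }
    protein_matrix = reciprocal_search(focal_orf_sequences, other_sets, setting)
    marine = [sp for sp in bundle.config.species if sp != sd.TERRESTRIAL]
    protein_cs = core_sets(protein_matrix, sd.FOCAL, list(bundle.config.species), marine)

    profiles = load_profiles()
    species_for_domains = dict(other_sets)
    species_for_domains[sd.FOCAL] = focal_orf_sequences
    annotations = annotate_species_domains(species_for_domains, profiles)
    domain_matrix = domain_presence_matrix(
        annotations, features=sorted(truth.domain_truth)
    )
    domain_cs = core_sets(domain_matrix, sd.FOCAL, list(bundle.config.species), marine)

    tree = load_species_tree()
    ancestral = dollo_ancestral(tree, domain_matrix)

    recovery = score_recovery(
        truth, accepted, excluded, rejected, protein_cs, domain_matrix, ancestral
    )
    return PipelineResult(
        bundle, stats, candidates, psms, accepted, excluded, rejected,
        focal_orf_sequences, protein_matrix, protein_cs, domain_matrix,
        domain_cs, ancestral, recovery,
    )


def _set_agreement_pct(found, expected) -> float:
    found, expected = set(found), set(expected)
    if not found and not expected:
        return 100.0
    return 100.0 * len(found & expected) / len(found | expected)


def score_recovery(
    truth: sd.GroundTruth,
    accepted: list,
    excluded: list,
    rejected: list,
    protein_cs: CoreSets,
    domain_matrix: PresenceMatrix,
    ancestral,
) -> dict:
    """Exact-recovery percentages of every planted structure."""
    labels = protein_cs.classify()
    classified = {
        pid: labels.get(pid, "missing") for pid in labels
    }
    expected_class = {}
    for cid in truth.expected_accepted:
        pid = truth.contigs[cid]["protein_id"]
        cls = truth.protein_class(pid)
        expected_class[pid] = (
            f"pair_shared:{sd.PAIR_PARTNER}" if cls == "pair_shared" else cls
        )
    n_class_ok = sum(
        1 for pid, cls in expected_class.items() if classified.get(pid) == cls
    )
    coreset_pct = 100.0 * n_class_ok / len(expected_class) if expected_class else 100.0

    truth_cells = {
        (d, sp): sp in set(sps) for d, sps in truth.domain_truth.items()
        for sp in domain_matrix.species
    }
    n_cells = len(truth_cells)
    n_cell_ok = sum(
        1 for (d, sp), v in truth_cells.items() if domain_matrix.cell(d, sp) == v
    )
    expected_root = {
        d for d, sps in truth.domain_truth.items()
        if set(sps) >= set(sd.MARINE)
    }
    return {
        "accepted_recovery_pct": _set_agreement_pct(accepted, truth.expected_accepted),
        "excluded_recovery_pct": _set_agreement_pct(excluded, truth.expected_excluded),
        "rejected_recovery_pct": _set_agreement_pct(rejected, truth.expected_rejected),
        "coreset_classification_pct": coreset_pct,
        "domain_matrix_pct": 100.0 * n_cell_ok / n_cells if n_cells else 100.0,
        "dollo_root_pct": _set_agreement_pct(
            ancestral.root_present_features(), expected_root
        ),
        "n_accepted": len(accepted),
        "n_excluded": len(excluded),
        "n_rejected": len(rejected),
    }


def psm_score_experiment(
    seed: int = 42, n_spectra: int = 100, dropout: float = 0.5
) -> float:
    """Mean matched-ion-fraction score over noise-free spectra whose ladders
    lose each peak with probability ``dropout`` — the expected mean equals
    the survival rate 1 - dropout."""
    config = sd.SimConfig(
        seed=seed,
        fragment_dropout=dropout,
        noise_peak_rate=0.0,
        precursor_jitter_ppm=0.0,
    )
    rng = np.random.default_rng(seed)
    species_sets, truth = sd.simulate_species_sets(config, rng)
    proteins = species_sets[sd.FOCAL]
    index = build_peptide_index(proteins)
    scores = []
    pids = sorted(proteins)
    i = 0
    while len(scores) < n_spectra:
        pid = pids[i % len(pids)]
        i += 1
        pool = sd._eligible_peptides(proteins[pid])
        if not pool:
            continue
        pep = pool[int(rng.integers(0, len(pool)))]
        spectrum = sd._render_spectrum(pep, f"exp|{pid}|{i}", config, rng)
        psm = match_spectrum(spectrum, index)
        if psm is not None and psm.peptide.sequence == pep.sequence:
            scores.append(psm.score)
    return float(np.mean(scores))
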