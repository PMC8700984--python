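"""Synthetic study inputs with planted ground truth, plus transcribed fixtures.

The generator emulates the inputs of a shell proteotranscriptomics study at
desk scale: fragmented mantle-transcriptome contigs encoding shell matrix
proteins (SMPs) flanked by untranslated padding, a minority of contigs
carrying a single frameshift indel inside the CDS, tryptic MS/MS spectra
(b/y ladders with peak dropout and noise) for a subset of encoded proteins,
and five species' SMP protein sets with planted homology structure — an
all-conchiferan core, a marine-only core, focal+partner pair-shared
proteins, and focal-specific proteins — with domain motifs planted per
family architecture. Every dataset is serialized alongside its GroundTruth
so each pipeline stage can be scored exactly.

Defaults mirror the study conditions: 60 SMP proteins of which a fraction
14/61 carry frameshifts, at least two spectra per true SMP, five species
(one terrestrial), core structure {3 shared by all, 5 marine-only, 2 shared
with Lottia}, and 70% homolog identity.
"""

from __future__ import annotations

import hashlib
import json
import warnings
from dataclasses import dataclass, field, asdict
from importlib import resources
from typing import Optional

import numpy as np
import pandas as pd
from Bio.Data.CodonTable import unambiguous_dna_by_id
from Bio.Align import substitution_matrices

from .transcript_orf import Contig
from .proteome_match import (
    PROTON,
    Peptide,
    Spectrum,
    digest_tryptic,
    fragment_ions,
)
from .homology_coresets import PresenceMatrix

AA20 = "ACDEFGHIKLMNPQRSTVWY"

SPECIES = ("Nautilus", "Crassostrea", "Pinctada", "Lottia", "Euhadra")
MARINE = ("Nautilus", "Crassostrea", "Pinctada", "Lottia")
FOCAL = "Nautilus"
TERRESTRIAL = "Euhadra"
PAIR_PARTNER = "Lottia"

#: N-terminal secretion-signal prefix planted on secreted families:
#: charged n-region, leucine h-region, A-S-A cleavage motif.
SIGNAL_PREFIX = "MKKLLLLLLLLLLASA"

#: Domain architectures of the planted families (ordered motif lists).
DEFAULT_ARCHITECTURES = {
    "smp_all_00": ["Signal Peptide", "VWA", "ChtBD2"],
    "smp_all_01": ["Signal Peptide", "A2M_comp", "A2M_recep"],
    "smp_all_02": ["Signal Peptide", "Tyrosinase"],
    "smp_marine_00": ["An_Peroxidase"],
    "smp_marine_01": ["Glyco_18"],
    "smp_marine_02": ["ZP", "EGF"],
    "smp_marine_03": ["KU"],
    "smp_marine_04": ["Thiol-ester_cl"],
}


@dataclass
class SimConfig:
    seed: int = 42
    n_smp_proteins: int = 60
    n_decoy_contigs: int = 40
    frac_frameshift: float = 14 / 61
    spectra_per_smp: int = 3
    n_single_peptide_smps: int = 0
    fragment_dropout: float = 0.1
    noise_peak_rate: float = 0.1
    precursor_jitter_ppm: float = 3.0
    species: tuple = SPECIES
    core_structure: dict = field(
        default_factory=lambda: {"shared_all": 3, "marine_only": 5, "pair_shared": 2}
    )
    homolog_identity: float = 0.70
    protein_len_range: tuple = (240, 320)
    n_other_specific: int = 8  # extra species-specific proteins per non-focal species
    utr_len_range: tuple = (0, 150)
    decoy_len_range: tuple = (200, 800)

    def __post_init__(self):
        if not 0.0 <= self.frac_frameshift <= 1.0:
            raise ValueError("frac_frameshift must be in [0,1]")
        n_core = sum(self.core_structure.values())
        if n_core > self.n_smp_proteins:
            raise ValueError("core structure counts exceed n_smp_proteins")
        if self.homolog_identity <= 0.05:
            raise ValueError("homolog_identity at or below random expectation")
        n_focal_specific = self.n_smp_proteins - n_core
        if round(self.frac_frameshift * self.n_smp_proteins) > n_focal_specific:
            raise ValueError("not enough focal-specific proteins to host frameshifts")

    @property
    def n_frameshift(self) -> int:
        return round(self.frac_frameshift * self.n_smp_proteins)


@dataclass
class GroundTruth:
    """Planted truth serialized alongside every simulated dataset."""

    proteins: dict = field(default_factory=dict)  # pid -> {class, species, domains, length}
    contigs: dict = field(default_factory=dict)  # contig_id -> {protein_id, cds_frame, frameshift, ...}
    domain_truth: dict = field(default_factory=dict)  # domain -> sorted list of species
    expected_accepted: list = field(default_factory=list)  # contig ids
    expected_excluded: list = field(default_factory=list)
    expected_rejected: list = field(default_factory=list)

    def protein_class(self, pid: str) -> str:
        return self.proteins[pid]["class"]

    def contig_for_protein(self, pid: str) -> Optional[str]:
        for cid, info in self.contigs.items():
            if info["protein_id"] == pid:
                return cid
        return None

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=1)


_BLOSUM = substitution_matrices.load("BLOSUM62")


def _substitution_targets() -> dict[str, list[str]]:
    """For each residue, the non-identical residues with the best BLOSUM62
    score (the substitutions divergence is biased toward)."""
    targets = {}
    for a in AA20:
        scores = sorted(
            ((_BLOSUM[a, b], b) for b in AA20 if b != a), reverse=True
        )
        best = scores[0][0]
        targets[a] = [b for s, b in scores if s >= best - 1]
    return targets


_SUB_TARGETS = _substitution_targets()


def random_protein(rng: np.random.Generator, length: int) -> str:
    return "".join(rng.choice(list(AA20), size=length))


def mutate_to_identity(
    sequence: str,
    identity: float,
    rng: np.random.Generator,
    protected: Optional[set[int]] = None,
) -> str:
    """Substitute residues i.i.d. (no indels) until the target global identity.

    Positions in ``protected`` (planted motifs, the signal prefix) are never
    touched; replacements are drawn from the BLOSUM62-favored partners of the
    original residue, so divergent homologs still align well.
    """
    protected = protected or set()
    n_mut = round((1.0 - identity) * len(sequence))
    candidates = [i for i in range(len(sequence)) if i not in protected]
    n_mut = min(n_mut, len(candidates))
    sites = rng.choice(len(candidates), size=n_mut, replace=False) if n_mut else []
    seq = list(sequence)
    for k in sites:
        i = candidates[int(k)]
        seq[i] = rng.choice(_SUB_TARGETS[seq[i]])
    return "".join(seq)


def _plant_domains(
    rng: np.random.Generator,
    length: int,
    architecture: list[str],
    consensus: dict[str, str],
) -> tuple[str, set[int], list[tuple[str, int, int]]]:
    """A random protein with the architecture's motifs stamped in, the set of
    protected positions, and the planted (domain, start, end) coordinates."""
    seq = list(random_protein(rng, length))
    protected: set[int] = set()
    placed: list[tuple[str, int, int]] = []
    pos = 0
    if architecture and architecture[0] == "Signal Peptide":
        seq[: len(SIGNAL_PREFIX)] = SIGNAL_PREFIX
        protected.update(range(len(SIGNAL_PREFIX)))
        placed.append(("Signal Peptide", 0, len(SIGNAL_PREFIX)))
        pos = len(SIGNAL_PREFIX) + 10
        rest = architecture[1:]
    else:
        pos = 15
        rest = architecture
    for name in rest:
        motif = consensus[name]
        start = pos + int(rng.integers(0, 8))
        end = start + len(motif)
        if end > length:
            raise ValueError("protein too short for its domain architecture")
        seq[start:end] = motif
        protected.update(range(start, end))
        placed.append((name, start, end))
        pos = end + 20
    return "".join(seq), protected, placed


def _load_consensus() -> dict[str, str]:
    ref = resources.files("conchicore.fixtures") / "domain_profiles_synthetic.json"
    raw = json.loads(ref.read_text())
    return {p["name"]: p["consensus"] for p in raw["profiles"]}


def simulate_species_sets(
    config: SimConfig, rng: Optional[np.random.Generator] = None
) -> tuple[dict[str, dict[str, str]], GroundTruth]:
    """Five species' SMP protein sets with planted core structure.

    Shared families descend from a root sequence (kept verbatim in the focal
    species) mutated per species to the target homolog identity outside
    planted motifs; focal-specific and other-species-specific proteins are
    unrelated random sequences.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    consensus = _load_consensus()
    truth = GroundTruth()
    marine = [sp for sp in config.species if sp != TERRESTRIAL]
    lo, hi = config.protein_len_range
    species_sets: dict[str, dict[str, str]] = {sp: {} for sp in config.species}

    def family_species(cls: str) -> list[str]:
        if cls == "shared_all":
            return list(config.species)
        if cls == "marine_only":
            return marine
        if cls == "pair_shared":
            return [FOCAL, PAIR_PARTNER]
        return [FOCAL]

    n_core = config.core_structure
    plan = (
        [("shared_all", f"smp_all_{i:02d}") for i in range(n_core["shared_all"])]
        + [("marine_only", f"smp_marine_{i:02d}") for i in range(n_core["marine_only"])]
        + [("pair_shared", f"smp_pair_{i:02d}") for i in range(n_core["pair_shared"])]
        + [
            ("focal_specific", f"smp_focal_{i:02d}")
            for i in range(config.n_smp_proteins - sum(n_core.values()))
        ]
    )
    for cls, pid in plan:
        length = int(rng.integers(lo, hi + 1))
        architecture = DEFAULT_ARCHITECTURES.get(pid, [])
        root, protected, placed = _plant_domains(rng, length, architecture, consensus)
        members = family_species(cls)
        for sp in members:
            if sp == FOCAL:
                species_sets[sp][pid] = root
            else:
                species_sets[sp][f"{sp}|{pid}"] = mutate_to_identity(
                    root, config.homolog_identity, rng, protected
                )
        truth.proteins[pid] = {
            "class": cls,
            "species": members,
            "domains": [d for d, _, _ in placed],
            "domain_coords": placed,
            "length": length,
        }
    for sp in config.species:
        if sp == FOCAL:
            continue
        for i in range(config.n_other_specific):
            length = int(rng.integers(lo, hi + 1))
            species_sets[sp][f"{sp}|specific_{i:02d}"] = random_protein(rng, length)
    # species-level domain truth implied by the planted architectures
    domain_truth: dict[str, set] = {}
    for pid, info in truth.proteins.items():
        for d in info["domains"]:
            domain_truth.setdefault(d, set()).update(info["species"])
    truth.domain_truth = {d: sorted(sps) for d, sps in sorted(domain_truth.items())}
    return species_sets, truth


_CODONS = {
    aa: sorted(c for c, a in unambiguous_dna_by_id[1].forward_table.items() if a == aa)
    for aa in AA20
}


def back_translate(protein: str, rng: np.random.Generator) -> str:
    """Uniform random choice among synonymous codons (seeded)."""
    return "".join(rng.choice(_CODONS[a]) for a in protein)


def _random_nt(rng: np.random.Generator, n: int) -> str:
    return "".join(rng.choice(list("ACGT"), size=n))


def simulate_transcriptome(
    config: SimConfig,
    focal_proteins: dict[str, str],
    truth: GroundTruth,
    rng: np.random.Generator,
) -> list[Contig]:
    """Contigs encoding the focal SMPs plus unrelated decoy contigs.

    Each SMP ORF is back-translated, framed by a stop codon on either side of
    the CDS and padded with random UTR sequence, so the stop-delimited ORF of
    the encoding frame reproduces the protein exactly. Frameshift contigs
    (drawn from the focal-specific class) carry one inserted nucleotide at a
    codon boundary near the middle of the CDS, splitting the protein across
    two reading frames.
    """
    utr_lo, utr_hi = config.utr_len_range
    fs_pids = [p for p, info in truth.proteins.items() if info["class"] == "focal_specific"]
    fs_pids = fs_pids[: config.n_frameshift]
    single_pids = [
        p for p, info in truth.proteins.items()
        if info["class"] == "focal_specific" and p not in fs_pids
    ][: config.n_single_peptide_smps]
    contigs = []
    for k, (pid, protein) in enumerate(sorted(focal_proteins.items())):
        cds = back_translate(protein, rng)
        n5 = int(rng.integers(utr_lo // 3, utr_hi // 3 + 1))  # codon-aligned UTR
        utr5 = (_random_nt(rng, 3 * (n5 - 1)) + "TAA") if n5 else ""
        # off-phase pad so the CDS lands in any of the three forward frames
        utr5 = _random_nt(rng, int(rng.integers(0, 3))) + utr5
        utr3 = "TAA" + _random_nt(rng, int(rng.integers(utr_lo, utr_hi + 1)))
        frameshift = pid in fs_pids
        indel_aa = None
        if frameshift:
            indel_aa = int(rng.integers(110, len(protein) - 110 + 1))
            cds = cds[: 3 * indel_aa] + str(rng.choice(list("ACGT"))) + cds[3 * indel_aa:]
        seq = utr5 + cds + utr3
        cid = f"contig_{k:04d}"
        contigs.append(Contig(cid, seq))
        truth.contigs[cid] = {
            "protein_id": pid,
            "cds_offset": len(utr5),
            "frameshift": frameshift,
            "indel_aa": indel_aa,
            "single_peptide": pid in single_pids,
        }
        if frameshift:
            truth.expected_excluded.append(cid)
        elif pid in single_pids:
            truth.expected_rejected.append(cid)
        else:
            truth.expected_accepted.append(cid)
    for k in range(config.n_decoy_contigs):
        n = int(rng.integers(*config.decoy_len_range))
        contigs.append(Contig(f"decoy_{k:04d}", _random_nt(rng, n)))
    return contigs


def _eligible_peptides(protein: str, lo: int = None, hi: int = None) -> list[Peptide]:
    """Distinct tryptic peptides usable as spectrum sources, optionally
    restricted to [lo, hi) with one residue of intact cleavage context."""
    peps = digest_tryptic(protein, "", max_missed_cleavages=1, min_len=6, max_len=50)
    out = []
    seen = set()
    for p in peps:
        if p.mono_mass is None or p.sequence in seen:
            continue
        if lo is not None and p.start < lo + 1:
            continue
        if hi is not None and p.start + len(p.sequence) > hi - 1:
            continue
        seen.add(p.sequence)
        out.append(p)
    return out


def simulate_spectra(
    config: SimConfig,
    focal_proteins: dict[str, str],
    truth: GroundTruth,
    rng: np.random.Generator,
) -> list[Spectrum]:
    """Tryptic b/y-ladder spectra for the planted SMPs.

    True SMPs get ``spectra_per_smp`` spectra of distinct peptides; planted
    rejects get one; frameshifted proteins get peptides drawn from both sides
    of the indel so the matching stage sees two reading frames. Ladders
    suffer peak dropout at ``fragment_dropout`` and gain noise peaks at
    ``noise_peak_rate`` per theoretical ion.
    """
    spectra = []
    for cid in sorted(truth.contigs):
        info = truth.contigs[cid]
        pid = info["protein_id"]
        protein = focal_proteins[pid]
        if info["frameshift"]:
            p_aa = info["indel_aa"]
            prefix = _eligible_peptides(protein, hi=p_aa)
            suffix = _eligible_peptides(protein, lo=p_aa + 1)
            n_pre = max(1, config.spectra_per_smp // 2)
            n_suf = max(1, config.spectra_per_smp - n_pre)
            chosen = _pick(prefix, n_pre, rng, pid) + _pick(suffix, n_suf, rng, pid)
        else:
            pool = _eligible_peptides(protein)
            n = 1 if info["single_peptide"] else config.spectra_per_smp
            chosen = _pick(pool, n, rng, pid)
        for k, pep in enumerate(chosen):
            spectra.append(_render_spectrum(pep, f"spec|{pid}|{k}", config, rng))
    return spectra


def _pick(pool: list[Peptide], n: int, rng: np.random.Generator, pid: str) -> list[Peptide]:
    if len(pool) < n:
        warnings.warn(f"{pid}: only {len(pool)} eligible peptides for {n} spectra")
        n = len(pool)
    idx = rng.choice(len(pool), size=n, replace=False)
    return [pool[int(i)] for i in sorted(idx)]


def _render_spectrum(
    peptide: Peptide, spec_id: str, config: SimConfig, rng: np.random.Generator
) -> Spectrum:
    ions = fragment_ions(peptide.sequence)
    keep = [mz for _, _, mz in ions if rng.random() >= config.fragment_dropout]
    if len(keep) < 2:
        keep = [mz for _, _, mz in ions]
    n_noise = round(config.noise_peak_rate * len(ions))
    charge = 2
    precursor_mz = (peptide.mono_mass + charge * PROTON) / charge
    noise = rng.uniform(150.0, peptide.mono_mass, size=n_noise).tolist()
    mz = np.array(keep + noise)
    intensity = np.concatenate(
        [rng.uniform(100, 1000, size=len(keep)), rng.uniform(10, 100, size=n_noise)]
    )
    order = np.argsort(mz)
    jitter = rng.uniform(-config.precursor_jitter_ppm, config.precursor_jitter_ppm)
    precursor_mz *= 1.0 + jitter * 1e-6
    return Spectrum(spec_id, precursor_mz, charge, mz[order], intensity[order])


@dataclass
class SimBundle:
    config: SimConfig
    species_sets: dict
    contigs: list
    spectra: list
    truth: GroundTruth

    @property
    def focal_proteins(self) -> dict[str, str]:
        return self.species_sets[FOCAL]


def simulate_all(config: Optional[SimConfig] = None) -> SimBundle:
    """Generate every pipeline input from one seed (byte-deterministic)."""
    config = config or SimConfig()
    rng = np.random.default_rng(config.seed)
    species_sets, truth = simulate_species_sets(config, rng)
    contigs = simulate_transcriptome(config, species_sets[FOCAL], truth, rng)
    spectra = simulate_spectra(config, species_sets[FOCAL], truth, rng)
    return SimBundle(config, species_sets, contigs, spectra, truth)


# ---------------------------------------------------------------------------
# transcribed fixtures

_FIXTURES = "conchicore.fixtures"


def _read_fixture(filename: str) -> bytes:
    ref = resources.files(_FIXTURES) / filename
    data = ref.read_bytes()
    manifest = json.loads((resources.files(_FIXTURES) / "manifest.json").read_text())
    digest = hashlib.sha256(data).hexdigest()
    if manifest.get(filename) != digest:
        raise ValueError(f"fixture {filename}: checksum mismatch")
    return data


def load_fixtures(name: str):
    """Load a bundled transcribed fixture by name.

    Names: ``table1`` (47-contig annotation DataFrame),
    ``coreset_proteins_setting2`` (protein PresenceMatrix), ``shared_domains``
    (domain PresenceMatrix), ``species_tree`` (Newick text).
    """
    if name == "table1":
        import io

        df = pd.read_csv(
            io.BytesIO(_read_fixture("table1.tsv")),
            sep="\t",
            comment="#",
            dtype={"contig_id": str, "annotation": str},
            keep_default_na=False,  # "None" is a value, not missing data
        )
        df["fpkm"] = pd.to_numeric(df["fpkm"])
        df["evalue"] = pd.to_numeric(df["evalue"].replace("", None))
        if len(df) != 47:
            raise ValueError("table1 fixture must have 47 rows")
        return df
    if name == "coreset_proteins_setting2":
        raw = json.loads(_read_fixture("coreset_proteins_setting2.json"))
        return PresenceMatrix.from_dict(raw["proteins"], raw["species"])
    if name == "shared_domains":
        raw = json.loads(_read_fixture("shared_domains.json"))
        return PresenceMatrix.from_dict(raw["domains"], raw["species"])
    if name == "species_tree":
        return _read_fixture("conchifera.nwk").decode()
    raise KeyError(name)
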