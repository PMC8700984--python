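"""Proteogenomic matching: tryptic digestion, b/y ladders, PSMs, SMP inference.

Translated contig ORFs are digested in silico with trypsin, theoretical
monoisotopic masses and singly charged b/y fragment ladders are computed, and
experimental MS/MS spectra are matched against a mass-indexed peptide
collection. The spectrum score is the matched-ion fraction: the share of the
theoretical b/y ions found in the spectrum within the fragment tolerance.
Contigs supported by at least two distinct peptides in exactly one reading
frame are promoted to shell-matrix-protein (SMP) candidates; contigs with
confident matches in two or more frames are flagged as likely frameshift
artifacts and excluded from downstream comparison.
"""

from __future__ import annotations

import warnings
from bisect import bisect_left, bisect_right
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import numpy as np

from .transcript_orf import parse_orf_id

WATER = 18.010565
PROTON = 1.007276

#: Monoisotopic residue masses (Da) for the 20 standard amino acids.
MONO_MASS = {
    "G": 57.02146, "A": 71.03711, "S": 87.03203, "P": 97.05276, "V": 99.06841,
    "T": 101.04768, "C": 103.00919, "L": 113.08406, "I": 113.08406,
    "N": 114.04293, "D": 115.02694, "Q": 128.05858, "K": 128.09496,
    "E": 129.04259, "M": 131.04049, "H": 137.05891, "F": 147.06841,
    "R": 156.10111, "Y": 163.06333, "W": 186.07931,
}


@dataclass(frozen=True)
class Peptide:
    sequence: str
    parent_protein_id: str
    start: int  # aa offset within the parent
    missed_cleavages: int
    mono_mass: Optional[float]  # None when the sequence has nonstandard residues


@dataclass
class Spectrum:
    id: str
    precursor_mz: float
    precursor_charge: int
    peaks_mz: np.ndarray  # sorted ascending
    peaks_intensity: np.ndarray

    @property
    def neutral_mass(self) -> float:
        return (self.precursor_mz - PROTON) * self.precursor_charge


@dataclass(frozen=True)
class Psm:
    spectrum_id: str
    peptide: Peptide
    score: float
    precursor_error_ppm: float


@dataclass(frozen=True)
class SmpCandidate:
    contig_id: str
    frames: tuple[int, ...]
    distinct_peptides: int
    status: str  # accepted_single_frame | excluded_multi_frame | rejected_insufficient_peptides


def peptide_mono_mass(sequence: str) -> float:
    """Monoisotopic neutral mass: residue masses plus one water."""
    try:
        return sum(MONO_MASS[a] for a in sequence) + WATER
    except KeyError as exc:
        raise ValueError(f"nonstandard residue {exc.args[0]!r} in {sequence!r}") from None


def _cleavage_sites(protein: str) -> list[int]:
    """Positions i such that trypsin cuts after residue i-1 (K/R not before P)."""
    return [
        i + 1
        for i in range(len(protein) - 1)
        if protein[i] in "KR" and protein[i + 1] != "P"
    ]


def digest_tryptic(
    protein: str,
    parent_protein_id: str = "",
    max_missed_cleavages: int = 2,
    min_len: Optional[int] = 6,
    max_len: Optional[int] = 50,
) -> list[Peptide]:
    """Tryptic peptides of a protein: cleave after K/R unless followed by P.

    All peptides with up to ``max_missed_cleavages`` internal missed cleavage
    sites and length inside [min_len, max_len] are returned (bounds of None
    disable the corresponding filter). Peptides containing nonstandard
    residues (X, B, Z, ...) carry ``mono_mass=None``.
    """
    if not protein:
        raise ValueError("empty protein")
    bounds = [0] + _cleavage_sites(protein) + [len(protein)]
    peptides = []
    for i in range(len(bounds) - 1):
        for mc in range(max_missed_cleavages + 1):
            j = i + mc + 1
            if j >= len(bounds):
                break
            seq = protein[bounds[i]:bounds[j]]
            if min_len is not None and len(seq) < min_len:
                continue
            if max_len is not None and len(seq) > max_len:
                continue
            try:
                mass = peptide_mono_mass(seq)
            except ValueError:
                mass = None
            peptides.append(Peptide(seq, parent_protein_id, bounds[i], mc, mass))
    return peptides


def fragment_ions(sequence: str) -> list[tuple[str, int, float]]:
    """Singly charged b and y fragment ions of a peptide.

    b_i = sum of the first i residues + proton; y_j = sum of the last j
    residues + water + proton, for i, j in 1..n-1.
    """
    n = len(sequence)
    if n < 2:
        raise ValueError("peptide must have >= 2 residues")
    masses = [MONO_MASS[a] for a in sequence]
    ions = []
    acc = 0.0
    for i in range(n - 1):
        acc += masses[i]
        ions.append(("b", i + 1, acc + PROTON))
    acc = 0.0
    for j in range(n - 1):
        acc += masses[n - 1 - j]
        ions.append(("y", j + 1, acc + WATER + PROTON))
    return ions


class PeptideIndex:
    """Peptide collection indexed by neutral monoisotopic mass."""

    def __init__(self, peptides: Iterable[Peptide]):
        usable = [p for p in peptides if p.mono_mass is not None]
        self.peptides = sorted(usable, key=lambda p: p.mono_mass)
        self._masses = [p.mono_mass for p in self.peptides]

    def __len__(self) -> int:
        return len(self.peptides)

    def query(self, neutral_mass: float, tol_ppm: float) -> list[Peptide]:
        tol = neutral_mass * tol_ppm * 1e-6
        lo = bisect_left(self._masses, neutral_mass - tol)
        hi = bisect_right(self._masses, neutral_mass + tol)
        return self.peptides[lo:hi]


def build_peptide_index(
    orf_sequences: dict[str, str],
    max_missed_cleavages: int = 2,
    min_len: int = 6,
    max_len: int = 50,
) -> PeptideIndex:
    """Digest every ORF and index the resulting peptides by mass.

    Peptides with nonstandard residues (e.g. X from N-containing codons) are
    skipped with a warning; X never matches downstream.
    """
    peptides: list[Peptide] = []
    n_skipped = 0
    for pid, seq in orf_sequences.items():
        for pep in digest_tryptic(seq, pid, max_missed_cleavages, min_len, max_len):
            if pep.mono_mass is None:
                n_skipped += 1
            else:
                peptides.append(pep)
    if n_skipped:
        warnings.warn(f"skipped {n_skipped} peptides with nonstandard residues")
    return PeptideIndex(peptides)


def _score_peptide(spectrum: Spectrum, sequence: str, fragment_tol_da: float) -> float:
    ions = fragment_ions(sequence)
    if spectrum.peaks_mz.size == 0:
        return 0.0
    mzs = spectrum.peaks_mz
    matched = 0
    for _, _, mz in ions:
        i = np.searchsorted(mzs, mz)
        near = []
        if i < mzs.size:
            near.append(abs(mzs[i] - mz))
        if i > 0:
            near.append(abs(mzs[i - 1] - mz))
        if near and min(near) <= fragment_tol_da:
            matched += 1
    return matched / len(ions)


def match_spectrum(
    spectrum: Spectrum,
    index: PeptideIndex,
    precursor_tol_ppm: float = 10.0,
    fragment_tol_da: float = 0.5,
) -> Optional[Psm]:
    """Best peptide-spectrum match, or None.

    Only peptides whose neutral mass lies within the precursor tolerance are
    scored. Ties are broken deterministically: fewer missed cleavages first,
    then lexicographically smaller sequence, then parent id. A best score of
    zero is reported as no match.
    """
    neutral = spectrum.neutral_mass
    candidates = index.query(neutral, precursor_tol_ppm)
    if not candidates:
        return None
    best = None
    best_key = None
    for pep in candidates:
        score = _score_peptide(spectrum, pep.sequence, fragment_tol_da)
        key = (-score, pep.missed_cleavages, pep.sequence, pep.parent_protein_id)
        if best_key is None or key < best_key:
            best, best_key = pep, key
    score = -best_key[0]
    if score == 0.0:
        return None
    err_ppm = (neutral - best.mono_mass) / best.mono_mass * 1e6
    return Psm(spectrum.id, best, score, err_ppm)


def infer_smps(
    psms: Sequence[Psm],
    min_distinct_peptides: int = 2,
    min_score: float = 0.4,
    count_spectra: bool = False,
) -> list[SmpCandidate]:
    """Group confident PSMs by contig and apply the two-peptide rule.

    PSMs below ``min_score`` are dropped first; the multi-frame flag therefore
    operates on confident matches only. Support is counted as distinct peptide
    sequences by default (``count_spectra=True`` counts spectra instead).
    Contigs with confident PSMs in two or more reading frames are reported as
    ``excluded_multi_frame`` regardless of peptide count.
    """
    by_contig: dict[str, list[Psm]] = {}
    for psm in psms:
        if psm.score < min_score:
            continue
        contig_id, _, _, _ = parse_orf_id(psm.peptide.parent_protein_id)
        by_contig.setdefault(contig_id, []).append(psm)
    out = []
    for contig_id in sorted(by_contig):
        group = by_contig[contig_id]
        frames = tuple(sorted({parse_orf_id(p.peptide.parent_protein_id)[1] for p in group}))
        if count_spectra:
            n_support = len({p.spectrum_id for p in group})
        else:
            n_support = len({p.peptide.sequence for p in group})
        n_distinct = len({p.peptide.sequence for p in group})
        if len(frames) >= 2:
            status = "excluded_multi_frame"
        elif n_support >= min_distinct_peptides:
            status = "accepted_single_frame"
        else:
            status = "rejected_insufficient_peptides"
        out.append(SmpCandidate(contig_id, frames, n_distinct, status))
    return out


def read_mgf(path) -> list[Spectrum]:
    """Read spectra from an MGF file (pyteomics backend)."""
    from pyteomics import mgf

    spectra = []
    with mgf.read(str(path)) as reader:
        for entry in reader:
            params = entry["params"]
            charge = int(params.get("charge", [2])[0])
            mz = np.asarray(entry["m/z array"], dtype=float)
            inten = np.asarray(entry["intensity array"], dtype=float)
            order = np.argsort(mz)
            spectra.append(
                Spectrum(
                    id=str(params.get("title", f"spectrum_{len(spectra)}")),
                    precursor_mz=float(params["pepmass"][0]),
                    precursor_charge=charge,
                    peaks_mz=mz[order],
                    peaks_intensity=inten[order],
                )
            )
    return spectra


def write_mgf(spectra: Iterable[Spectrum], path) -> None:
    from pyteomics import mgf

    entries = [
        {
            "m/z array": s.peaks_mz,
            "intensity array": s.peaks_intensity,
            "params": {
                "title": s.id,
                "pepmass": s.precursor_mz,
                "charge": s.precursor_charge,
            },
        }
        for s in spectra
    ]
    mgf.write(entries, str(path), file_mode="w")
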