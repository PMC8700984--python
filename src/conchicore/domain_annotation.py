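"""Protein domain scanning with synthetic mini-profiles and a signal-peptide rule.

Domain presence is detected by scoring every window of a protein against
bundled position weight matrices (PWMs, log-odds in bits against a uniform
residue background) for the eleven domain families recurring in conchiferan
shell matrix proteins (A2M_comp, A2M_recep, ChtBD2, VWA, Tyrosinase,
An_Peroxidase, Glyco_18, ZP, EGF, KU, Thiol-ester_cl). The profiles are
synthetic stand-ins built around fixed consensus motifs — they capture the
presence/absence set logic of the comparative analysis, not curated HMM
fidelity — and each carries a threshold calibrated so that a full scan of a
random 300-residue protein produces a false hit in fewer than 1 in 10^4
scans (see scripts/build_domain_profiles.py for the seeded calibration).

Secretion signal peptides are called by a three-part heuristic (charged
n-region, hydrophobic h-region, A-X-A c-region) and treated as a twelfth
domain feature in the species-level presence matrix.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from importlib import resources
from typing import Iterable, Mapping, Optional

import numpy as np

from .homology_coresets import PresenceMatrix, core_sets, CoreSets

ALPHABET = "ACDEFGHIKLMNPQRSTVWY"
_AA_INDEX = {a: i for i, a in enumerate(ALPHABET)}

SIGNAL_PEPTIDE = "Signal Peptide"

#: Kyte-Doolittle hydropathy index.
KYTE_DOOLITTLE = {
    "I": 4.5, "V": 4.2, "L": 3.8, "F": 2.8, "C": 2.5, "M": 1.9, "A": 1.8,
    "G": -0.4, "T": -0.7, "S": -0.8, "W": -0.9, "Y": -1.3, "P": -1.6,
    "H": -3.2, "E": -3.5, "Q": -3.5, "D": -3.5, "N": -3.5, "K": -3.9,
    "R": -4.5,
}


@dataclass(frozen=True)
class DomainProfile:
    name: str
    pwm: np.ndarray  # (length, 20) log-odds in bits
    score_threshold: float
    consensus: str = ""

    @property
    def length(self) -> int:
        return self.pwm.shape[0]


@dataclass(frozen=True)
class DomainAnnotation:
    protein_id: str
    domain_name: str
    start: int  # 0-based half-open aa coordinates
    end: int
    score: float


@dataclass(frozen=True)
class SignalPeptideCall:
    protein_id: str
    present: bool
    cleavage_site: Optional[int]  # 0-based index of the first mature residue
    hydrophobicity_score: float
    reason: str = ""


def load_profiles(path=None) -> list[DomainProfile]:
    """Load the bundled (or a user-supplied) JSON PWM profile set."""
    if path is None:
        ref = resources.files("conchicore.fixtures") / "domain_profiles_synthetic.json"
        raw = json.loads(ref.read_text())
    else:
        with open(path) as fh:
            raw = json.load(fh)
    if raw["alphabet"] != ALPHABET:
        raise ValueError("profile alphabet mismatch")
    return [
        DomainProfile(
            name=p["name"],
            pwm=np.asarray(p["log_odds"], dtype=float),
            score_threshold=float(p["score_threshold"]),
            consensus=p.get("consensus", ""),
        )
        for p in raw["profiles"]
    ]


def encode_protein(protein: str) -> np.ndarray:
    """Map residues to alphabet indices; nonstandard residues become -1."""
    return np.array([_AA_INDEX.get(a, -1) for a in protein], dtype=int)


def _window_scores(encoded: np.ndarray, profile: DomainProfile) -> np.ndarray:
    """Score of every window; nonstandard residues contribute the column minimum."""
    L = profile.length
    n = encoded.size - L + 1
    if n <= 0:
        return np.empty(0)
    # pad the PWM with a worst-case column for nonstandard residues
    pwm = np.hstack([profile.pwm, profile.pwm.min(axis=1, keepdims=True)])
    windows = np.lib.stride_tricks.sliding_window_view(encoded, L)
    return pwm[np.arange(L), windows].sum(axis=1)


def scan_domains(
    protein: str,
    profiles: Iterable[DomainProfile],
    protein_id: str = "protein",
) -> list[DomainAnnotation]:
    """All above-threshold PWM windows, overlapping same-domain hits merged.

    For each profile every window scoring at or above the profile threshold
    is a candidate; candidates of the same domain that overlap are reduced to
    the best-scoring window (ties to the leftmost).
    """
    profiles = list(profiles)
    if not profiles:
        return []
    encoded = encode_protein(protein)
    annotations: list[DomainAnnotation] = []
    for profile in profiles:
        scores = _window_scores(encoded, profile)
        hits = [
            DomainAnnotation(protein_id, profile.name, s, s + profile.length, float(scores[s]))
            for s in np.nonzero(scores >= profile.score_threshold)[0]
        ]
        hits.sort(key=lambda h: (-h.score, h.start))
        kept: list[DomainAnnotation] = []
        for h in hits:
            if all(h.end <= k.start or h.start >= k.end for k in kept):
                kept.append(h)
        annotations.extend(sorted(kept, key=lambda h: h.start))
    return annotations


def predict_signal_peptide(protein: str, protein_id: str = "protein") -> SignalPeptideCall:
    """Tripartite secretion-signal heuristic.

    Present iff (i) at least one K/R within the first five residues
    (n-region), (ii) some 7-residue window within residues 6-20 (1-based) has
    mean Kyte-Doolittle hydropathy >= 2.0 (h-region), and (iii) small
    residues (A/G/S/C) occupy the -3 and -1 positions of the best-scoring
    candidate cleavage site in [10, 35] (A-X-A rule). The cleavage site is
    the 0-based index of the first mature residue.
    """
    if len(protein) < 25:
        return SignalPeptideCall(protein_id, False, None, 0.0, "protein shorter than 25 aa")
    kd = [KYTE_DOOLITTLE.get(a, -4.5) for a in protein]
    n_region = any(a in "KR" for a in protein[0:5])
    h_score = max(
        float(np.mean(kd[s:s + 7])) for s in range(5, 14)
    )
    h_region = h_score >= 2.0
    best_c, best_c_score = None, None
    for c in range(10, min(35, len(protein) - 1) + 1):
        if protein[c - 3] in "AGSC" and protein[c - 1] in "AGSC":
            c_score = float(np.mean(kd[max(0, c - 9):c - 3]))
            if best_c_score is None or c_score > best_c_score:
                best_c, best_c_score = c, c_score
    reasons = []
    if not n_region:
        reasons.append("no K/R in n-region")
    if not h_region:
        reasons.append("h-region hydropathy below 2.0")
    if best_c is None:
        reasons.append("no A-X-A cleavage site in [10,35]")
    present = not reasons
    return SignalPeptideCall(
        protein_id, present, best_c if present else None, h_score, "; ".join(reasons)
    )


def domain_presence_matrix(
    annotations_per_species: Mapping[str, Iterable[DomainAnnotation]],
    features: Optional[list[str]] = None,
) -> PresenceMatrix:
    """Species-level domain presence: a domain is present in a species iff at
    least one of its SMPs carries it (no count weighting)."""
    if len(annotations_per_species) < 1:
        raise ValueError("need at least one species")
    per_species = {
        sp: {a.domain_name for a in anns}
        for sp, anns in annotations_per_species.items()
    }
    if features is None:
        features = sorted(set().union(*per_species.values())) if per_species else []
    import pandas as pd

    df = pd.DataFrame(
        {sp: [d in per_species[sp] for d in features] for sp in per_species},
        index=features,
    )
    return PresenceMatrix(df)


def annotate_species_domains(
    species_sets: Mapping[str, Mapping[str, str]],
    profiles: Optional[list[DomainProfile]] = None,
    include_signal_peptide: bool = True,
) -> dict[str, list[DomainAnnotation]]:
    """Scan every protein of every species; signal peptides are recorded as a
    ``Signal Peptide`` domain annotation covering the pre-cleavage region."""
    if profiles is None:
        profiles = load_profiles()
    out: dict[str, list[DomainAnnotation]] = {}
    for sp, prots in species_sets.items():
        anns: list[DomainAnnotation] = []
        for pid, seq in prots.items():
            anns.extend(scan_domains(seq, profiles, pid))
            if include_signal_peptide:
                call = predict_signal_peptide(seq, pid)
                if call.present:
                    anns.append(
                        DomainAnnotation(pid, SIGNAL_PEPTIDE, 0, call.cleavage_site,
                                         call.hydrophobicity_score)
                    )
        out[sp] = anns
    return out


def shared_domain_sets(
    matrix: PresenceMatrix,
    focal: str,
    group_all: Iterable[str],
    group_marine: Iterable[str],
) -> CoreSets:
    """Core-set partition applied to domain features (same algorithm as for
    proteins)."""
    return core_sets(matrix, focal, group_all, group_marine)
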