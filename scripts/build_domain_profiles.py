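"""Build and calibrate the synthetic domain mini-profiles fixture.

Each of the eleven domain families is represented by a position weight
matrix built around a fixed consensus motif: the consensus residue gets
probability 0.70 at its position, the remaining mass 0.30 is spread evenly
over the other 19 residues, and scores are log2 odds against a uniform
background (1/20). The detection threshold is set at half the consensus
score and then verified by a seeded calibration: scanning 10,000 random
300-residue proteins per profile must produce zero above-threshold windows
(i.e. a false-positive rate below 1 per 10^4 protein scans).

Run from the repository root:

    python scripts/build_domain_profiles.py
"""

import json
import sys
from pathlib import Path

import numpy as np

sys.path.insert(0, str(Path(__file__).resolve().parents[1] / "src"))

from conchicore.domain_annotation import ALPHABET, DomainProfile, _window_scores, encode_protein

CONSENSUS = {
    "A2M_comp": "NEDSLVFVQTDKPIYK",
    "A2M_recep": "YTLRAVAQGSWTVTAK",
    "ChtBD2": "CAPGWSAYGDHCYKAF",
    "VWA": "DVVFLLDGSGSIGRSN",
    "Tyrosinase": "DPLFWLHHSNVDRLWA",
    "An_Peroxidase": "FGQFIDHDITLTPQSK",
    "Glyco_18": "FDGLDLDWEYPGGRGA",
    "ZP": "CTDSGYFVLVMSRCPA",
    "EGF": "CDPNPCQNGGTCVDGI",
    "KU": "GPCRAAFPRWYFDVEK",
    "Thiol-ester_cl": "GCGEQNMIGMTPTVIA",
}

CONSENSUS_PROB = 0.70
N_CALIBRATION_SCANS = 10_000
CALIBRATION_PROTEIN_LEN = 300
SEED = 20210901


def build_pwm(consensus: str) -> np.ndarray:
    L = len(consensus)
    background = 1.0 / 20
    pwm = np.full((L, 20), np.log2((1 - CONSENSUS_PROB) / 19 / background))
    for i, aa in enumerate(consensus):
        pwm[i, ALPHABET.index(aa)] = np.log2(CONSENSUS_PROB / background)
    return np.round(pwm, 4)


def main() -> None:
    rng = np.random.default_rng(SEED)
    profiles = []
    for name, consensus in CONSENSUS.items():
        pwm = build_pwm(consensus)
        consensus_score = float(pwm.max(axis=1).sum())
        threshold = round(0.5 * consensus_score, 4)
        profile = DomainProfile(name, pwm, threshold, consensus)
        # calibration: false hits must occur in < 1 per 10^4 random protein scans
        false_hits = 0
        max_random = -np.inf
        for _ in range(N_CALIBRATION_SCANS):
            prot = rng.integers(0, 20, CALIBRATION_PROTEIN_LEN)
            scores = _window_scores(prot, profile)
            max_random = max(max_random, float(scores.max()))
            if (scores >= threshold).any():
                false_hits += 1
        assert false_hits == 0, f"{name}: {false_hits} false-positive scans"
        print(
            f"{name:16s} consensus {consensus_score:6.2f} bits, threshold "
            f"{threshold:6.2f}, max random window {max_random:7.2f} "
            f"({N_CALIBRATION_SCANS} scans, 0 false hits)"
        )
        profiles.append(
            {
                "name": name,
                "consensus": consensus,
                "score_threshold": threshold,
                "calibration": {
                    "seed": SEED,
                    "n_scans": N_CALIBRATION_SCANS,
                    "protein_len": CALIBRATION_PROTEIN_LEN,
                    "false_positive_scans": false_hits,
                    "max_random_window_score": round(max_random, 4),
                },
                "log_odds": pwm.tolist(),
            }
        )
    out = {
        "alphabet": ALPHABET,
        "background": "uniform 1/20",
        "consensus_probability": CONSENSUS_PROB,
        "profiles": profiles,
    }
    dest = Path(__file__).resolve().parents[1] / "src/conchicore/fixtures/domain_profiles_synthetic.json"
    dest.write_text(json.dumps(out, indent=1))
    print(f"wrote {dest}")


if __name__ == "__main__":
    main()
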