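"""Domain presence across species and Dollo ancestral reconstruction.

Scans every species' SMP set with the bundled mini-profiles plus the
signal-peptide rule, builds the species x domain presence matrix, and
reconstructs ancestral domain states on the conchiferan species tree under
Dollo parsimony. Writes the matrix and per-node states.
"""

import sys
from pathlib import Path

sys.path.insert(0, str(Path(__file__).resolve().parents[1] / "src"))

import pandas as pd

from conchicore import pipeline
from conchicore.synthetic_data import SimConfig

ROOT = Path(__file__).resolve().parents[1]
RESULTS = ROOT / "results"


def main() -> None:
    RESULTS.mkdir(exist_ok=True)
    res = pipeline.run_end_to_end(SimConfig())
    res.domain_matrix.to_tsv(RESULTS / "05_domain_presence.tsv")
    anc = res.ancestral
    anc.to_frame().astype(int).to_csv(RESULTS / "05_ancestral_states.tsv", sep="\t")

    events = pd.DataFrame(
        {
            "domain": list(anc.gains),
            "gain_above": [anc.gains[d] for d in anc.gains],
            "losses_above": ["/".join(anc.losses[d]) or "-" for d in anc.gains],
        }
    )
    events.to_csv(RESULTS / "05_gain_loss_events.tsv", sep="\t", index=False)

    root = sorted(anc.root_present_features())
    print(f"Domains reconstructed as present in the ancestral conchiferan "
          f"({len(root)} of {len(res.domain_matrix.features)}):")
    print("  " + ", ".join(root))
    marine_only = [d for d in root if anc.losses[d]]
    print(f"\nDomains lost on the {'/'.join(set(sum((anc.losses[d] for d in marine_only), [])))} "
          f"lineage: {', '.join(sorted(marine_only))}")
    print(f"Domain matrix equals planted truth: {res.recovery['domain_matrix_pct']:.0f}% of cells")


if __name__ == "__main__":
    main()
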