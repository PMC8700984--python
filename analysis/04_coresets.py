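"""Cross-species reciprocal search and protein core-set extraction.

Runs the full pipeline to the comparison stage under both stringency
settings, partitions the accepted SMPs into conservation classes, and
checks the classes against the planted truth. Writes the presence matrices
and the class table.
"""

import sys
from pathlib import Path

sys.path.insert(0, str(Path(__file__).resolve().parents[1] / "src"))

import pandas as pd

from conchicore import pipeline
from conchicore.homology_coresets import SETTING1, SETTING2, core_sets, reciprocal_search
from conchicore.synthetic_data import SimConfig, TERRESTRIAL

ROOT = Path(__file__).resolve().parents[1]
RESULTS = ROOT / "results"


def main() -> None:
    RESULTS.mkdir(exist_ok=True)
    res = pipeline.run_end_to_end(SimConfig(), setting=SETTING2)
    res.protein_matrix.to_tsv(RESULTS / "04_protein_presence_setting2.tsv")

    species = list(res.bundle.config.species)
    marine = [sp for sp in species if sp != TERRESTRIAL]
    others = {sp: p for sp, p in res.bundle.species_sets.items() if sp != "Nautilus"}
    m1 = reciprocal_search(res.focal_orf_sequences, others, SETTING1)
    m1.to_tsv(RESULTS / "04_protein_presence_setting1.tsv")
    cs1 = core_sets(m1, "Nautilus", species, marine)

    truth = res.bundle.truth
    labels2 = res.protein_coresets.classify()
    labels1 = cs1.classify()
    rows = [
        {
            "protein_id": pid,
            "planted_class": truth.protein_class(pid),
            "setting2_class": labels2.get(pid, "missing"),
            "setting1_class": labels1.get(pid, "missing"),
        }
        for pid in sorted(res.focal_orf_sequences)
    ]
    df = pd.DataFrame(rows)
    df.to_csv(RESULTS / "04_coreset_classes.tsv", sep="\t", index=False)

    for name, cs in (("Setting 1", cs1), ("Setting 2", res.protein_coresets)):
        print(f"{name}: shared_all={len(cs.shared_all)}, "
              f"marine_only={len(cs.shared_marine_only)}, "
              f"pair_shared={sum(map(len, cs.pair_shared.values()))}, "
              f"focal_specific={len(cs.focal_specific)}")
    print(f"\nSetting-2 classification matches planted truth: "
          f"{res.recovery['coreset_classification_pct']:.0f}% of accepted SMPs")
    nested = ((~m1.data) | res.protein_matrix.data).values.all()
    print(f"Setting-1 presence cells nest inside Setting-2: {nested}")


if __name__ == "__main__":
    main()
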