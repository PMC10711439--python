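#!/usr/bin/env python
"""Survey RuvC/ZF fingerprints across a mixed synthetic protein database.

Plants the three fingerprint arrangements (DPG + alternative glutamate,
DΦG + alternative glutamate, canonical glutamate placement) in a sea of
decoys, classifies everything, and reports per-category fractions and
per-class recovery — the desk-scale analogue of tallying how rare the
DPG/E_alt combination is among TnpB-family homologs.

Writes results/fingerprint_survey.tsv and results/fingerprint_fractions.json.
"""

import json
import sys
from pathlib import Path

sys.path.insert(0, str(Path(__file__).resolve().parents[1] / "src"))

import fanzorkit.synthetic_data as sd
from fanzorkit.fingerprint import scan_database

OUT = Path(__file__).resolve().parents[1] / "results"
SEED = 20240

def main() -> None:
    records = []
    for k, (rc, ep, n) in enumerate(
        [("DPG", "E_alt", 10), ("DPhiG", "E_alt", 200), ("DPG", "E_can", 400)]
    ):
        fam = sd.gen_protein_family(
            sd.ProteinFamilyConfig(n_positives=n, n_decoys=0, ruvc1_class=rc,
                                   e_placement=ep, mutation_rate=0.05,
                                   seed=SEED + k)
        )
        records += [(f"{rc}_{ep}_{r.id}", r) for r in fam]
    decoys = sd.gen_protein_family(
        sd.ProteinFamilyConfig(n_positives=0, n_decoys=390, seed=SEED + 9)
    )
    records += [(r.id, r) for r in decoys]

    table, fractions = scan_database({rid: r.sequence for rid, r in records})
    truth = {rid: r.category for rid, r in records}
    table["truth"] = table["id"].map(truth)
    table["correct"] = table["category"] == table["truth"]

    OUT.mkdir(exist_ok=True)
    table.to_csv(OUT / "fingerprint_survey.tsv", sep="\t", index=False)
    (OUT / "fingerprint_fractions.json").write_text(
        json.dumps(fractions, indent=2, sort_keys=True)
    )
    print(f"{len(table)} proteins classified; accuracy {table['correct'].mean():.4f}")
    print("category fractions:")
    for cat, frac in sorted(fractions.items()):
        print(f"  {cat:<12} {frac:.3f}")
    print("The full fingerprint (DPG + E_alt + ZF) is deliberately rare here "
          f"({fractions['FANZOR_LIKE']:.1%}), mirroring its rarity in nature.")


if __name__ == "__main__":
    main()
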