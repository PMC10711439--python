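#!/usr/bin/env python
"""Co-conservation of transposase/nuclease pairs across elements.

Simulates elements whose TnpA and TnpB diverge on a shared clock,
computes percent-identity couples for every element pair, and contrasts
the coupled correlation with a shuffled-pairing control and with fully
uncoupled clocks.

Writes results/coconservation_pairs.tsv and results/coconservation_hist.tsv.
"""

import sys
from pathlib import Path

import numpy as np
import pandas as pd

sys.path.insert(0, str(Path(__file__).resolve().parents[1] / "src"))

import fanzorkit.synthetic_data as sd
from fanzorkit.coconservation import paired_identities, trim_columns

OUT = Path(__file__).resolve().parents[1] / "results"
SEED = 303


def main() -> None:
    fams = sd.gen_paired_families(
        sd.PairedFamilyConfig(n_elements=30, coupling=1.0,
                              shuffle_control=True, seed=SEED)
    )
    msa_a, _ = trim_columns(fams.msa_a, occupancy=0.9)
    msa_b, _ = trim_columns(fams.msa_b, occupancy=0.9)
    res = paired_identities(msa_a, msa_b, fams.pairing)
    shuf = paired_identities(msa_a, msa_b, fams.shuffled_pairing)

    uncoupled = sd.gen_paired_families(
        sd.PairedFamilyConfig(n_elements=30, coupling=0.0, seed=SEED + 1)
    )
    res0 = paired_identities(uncoupled.msa_a, uncoupled.msa_b, uncoupled.pairing)

    OUT.mkdir(exist_ok=True)
    res.pairs.to_csv(OUT / "coconservation_pairs.tsv", sep="\t",
                     index=False, float_format="%.3f")
    hist = pd.DataFrame(res.histogram2d.astype(int))
    hist.to_csv(OUT / "coconservation_hist.tsv", sep="\t")

    print(f"{len(res.pairs)} element pairs (n=30 elements)")
    print(f"coupled clocks:   Pearson r = {res.pearson_r:.3f}, "
          f"Spearman rho = {res.spearman_rho:.3f}")
    print(f"shuffled pairing: Pearson r = {shuf.pearson_r:.3f}")
    print(f"uncoupled clocks: Pearson r = {res0.pearson_r:.3f}")
    print("Shared divergence histories leave a strong identity-identity "
          "correlation that vanishes when the pairing (or the clock "
          "coupling) is broken.")


if __name__ == "__main__":
    main()
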