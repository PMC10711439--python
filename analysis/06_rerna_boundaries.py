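#!/usr/bin/env python
"""reRNA boundary mapping and pseudoknot compensation analysis.

Simulates merged small-RNA reads over a transposon locus whose reRNA
ends 15 nt past the target-site-duplication end, maps them, calls the
expressed interval from the coverage plateau, and measures the extension
past the TSD.  Then walks the 5-nt pseudoknot register: every
Watson-Crick pair is broken by a single point mutation and rescued by
the compensatory partner mutation.

Writes results/rerna_coverage.tsv and results/pk_compensation.tsv.
"""

import sys
from pathlib import Path

import numpy as np
import pandas as pd

sys.path.insert(0, str(Path(__file__).resolve().parents[1] / "src"))

import fanzorkit.rerna as rr
import fanzorkit.synthetic_data as sd

OUT = Path(__file__).resolve().parents[1] / "results"
SEED = 888


def main() -> None:
    rng = np.random.default_rng(SEED)
    locus = "".join(rng.choice(list("ACGT"), size=600))
    tsd_end = 250
    start, end = tsd_end + 15 - 150, tsd_end + 15        # 150 nt reRNA
    reads, _ = sd.gen_smallrna_reads(
        sd.SmallRnaSimConfig(locus=locus, rerna_start=start, rerna_end=end,
                             n_reads=1000, end_noise_sd=1.0, seed=SEED)
    )
    profile = rr.map_reads(reads, locus)
    call = rr.call_boundaries(profile)
    OUT.mkdir(exist_ok=True)
    pd.DataFrame({"pos": np.arange(len(locus)), "depth": profile.coverage}).to_csv(
        OUT / "rerna_coverage.tsv", sep="\t", index=False
    )
    ext = rr.extension_beyond(call.interval, tsd_end, "right")
    print(f"mapped {profile.n_mapped}/{len(reads)} reads; called interval "
          f"{call.interval} ({call.interval[1] - call.interval[0]} nt)")
    print(f"reRNA extends {ext:+d} nt beyond the TSD end at {tsd_end} — the "
          "scaffold reaches into the flanking sequence the transposase fixes")

    # pseudoknot register: 5 nt flanking the guide vs the apical loop
    seq = "GG" + "GAAAC" + "A" * 10 + "GUUUC" + "GG"
    region_a, region_b = (2, 7), (17, 22)
    flip = {"A": "C", "C": "A", "G": "U", "U": "G"}
    comp = {"A": "U", "U": "A", "G": "C", "C": "G"}
    rows = []
    for i in range(5):
        pos_b = region_b[0] + i
        pos_a = region_a[0] + (4 - i)
        mutated = list(seq)
        mutated[pos_b] = flip[mutated[pos_b]]
        broken = rr.pk_check("".join(mutated), region_a, region_b).n_wc
        mutated[pos_a] = comp[mutated[pos_b]]
        rescued = rr.pk_check("".join(mutated), region_a, region_b).n_wc
        rows.append({"register_pos": i, "wc_wildtype": 5,
                     "wc_disrupted": broken, "wc_rescued": rescued})
    df = pd.DataFrame(rows)
    df.to_csv(OUT / "pk_compensation.tsv", sep="\t", index=False)
    print(df.to_string(index=False))
    print("Each single mutation costs exactly one Watson-Crick pair; the "
          "compensatory partner mutation restores it at every register slot.")


if __name__ == "__main__":
    main()
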