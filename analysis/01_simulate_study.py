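#!/usr/bin/env python
"""Simulate the two-plex TMT study with known ground truth.

Generates 1000 proteins (100 truly changed, 1.5-4x, random direction),
two plexes (biological replicates, 2x batch factor on plex 2) with three
technical replicates each, 10% multiplicative noise, 5% dropout, and a
random COG annotation for each protein.  Writes the truth table, every
technical-replicate intensity matrix, and the annotation map under
results/sim/.
"""

from pathlib import Path

import numpy as np

import tmtquant as tq
from tmtquant.synthdata import write_psm_table, write_truth_table

OUT = Path(__file__).resolve().parent.parent / "results" / "sim"
SEED = 20190611

COG_POOL = [
    "carbohydrate transport and metabolism",
    "energy production and conversion",
    "lipid transport and metabolism",
    "secondary metabolite biosynthesis, transport and catabolism",
    "cell motility",
    "signal transduction mechanisms",
    "transcription",
    "function unknown",
]


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    config = tq.SimulationConfig(seed=SEED)
    truth = tq.simulate_truth(config)
    write_truth_table(truth, OUT / "truth.tsv")
    print(f"simulated {len(truth)} proteins, "
          f"{sum(t.is_differential for t in truth)} differential")

    for plex in ("plex1", "plex2"):
        for m in tq.simulate_plex(truth, plex, config):
            path = OUT / f"intensities_{plex}_{m.tech_replicate}.tsv"
            tq.write_protein_matrix(m, path)
            print(f"  {path.name}: {len(m.data)} proteins")

    # a small PSM-level export of one replicate, for the ingest walkthrough
    m = tq.simulate_plex(truth, "plex1", config)[0]
    sub = m.with_data(m.data.iloc[:50])
    from scipy import stats
    psms = tq.simulate_psm_table(
        sub, 3, stats.uniform(0, 100), stats.lognorm(1.0, scale=30), seed=SEED
    )
    write_psm_table(psms, OUT / "psms_plex1_rep1_subset.tsv")

    rng = np.random.default_rng(SEED)
    with open(OUT / "cog_map.tsv", "w") as fh:
        for t in truth:
            cats = rng.choice(COG_POOL, size=rng.integers(1, 3), replace=False)
            fh.write(f"{t.protein_id}\t{';'.join(cats)}\n")
    print("wrote truth, matrices, PSM subset and COG map to", OUT)


if __name__ == "__main__":
    main()
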