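#!/usr/bin/env python
"""Ingest the simulated study and run SL → TMM → IRS normalization.

Reads the technical-replicate matrices written by 01_simulate_study.py,
applies the complete-case filter (protein quantified in all three
technical replicates of a plex), averages technical replicates, reports
the plex overlap, normalizes across plexes and writes the log2 abundance
table plus every normalization factor under results/.
"""

import json
from pathlib import Path

import tmtquant as tq
from tmtquant.ingest import (
    average_technical,
    filter_complete,
    intersect_plexes,
    read_protein_matrix,
)
from tmtquant.normalize import run_normalization

ROOT = Path(__file__).resolve().parent.parent / "results"
SIM = ROOT / "sim"


def main() -> None:
    plexes = {}
    for plex in ("plex1", "plex2"):
        reps = [
            read_protein_matrix(
                SIM / f"intensities_{plex}_rep{r}.tsv",
                tq.default_design(plex),
                plex_id=plex,
                tech_replicate=f"rep{r}",
            )
            for r in (1, 2, 3)
        ]
        complete = filter_complete(reps)
        print(f"{plex}: {len(complete)} proteins complete in all 3 replicates")
        plexes[plex] = average_technical(reps, complete)

    overlap = intersect_plexes(plexes)
    print(f"plex overlap: {overlap.per_plex} -> {overlap.overlap_size} shared")

    table, report = run_normalization(plexes)
    table.values.to_csv(ROOT / "abundance_log2.tsv", sep="\t")

    factors = {
        "stages": report.stages_applied,
        "sample_loading": {
            f"{p}:{ch}": v for (p, ch), v in report.sl_factors.items()
        },
        "tmm": {f"{p}:{ch}": v for (p, ch), v in report.tmm_factors.items()},
    }
    with open(ROOT / "normalization_factors.json", "w") as fh:
        json.dump(factors, fh, indent=2)
    report.irs_factors.to_csv(ROOT / "irs_factors.tsv", sep="\t")
    print(f"wrote log2 abundance table ({table.values.shape[0]} proteins x "
          f"{table.values.shape[1]} columns) and factors to {ROOT}")


if __name__ == "__main__":
    main()
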