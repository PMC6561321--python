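#!/usr/bin/env python
"""Summarize differential proteins by COG functional category.

Joins the differential calls with the simulated protein → COG map and
writes the tidy per-category up/down counts per strain used for bar
plots.
"""

from pathlib import Path

import pandas as pd

import tmtquant as tq

ROOT = Path(__file__).resolve().parent.parent / "results"


def main() -> None:
    values = pd.read_csv(
        ROOT / "abundance_log2.tsv", sep="\t", header=[0, 1], index_col=0
    )
    table = tq.AbundanceTable(values=values)
    ratios = tq.control_relative_log2(table)
    anova = tq.anova_per_protein(table)
    records = tq.classify(ratios, anova["p_value"])

    annotations = tq.read_cog_map(ROOT / "sim" / "cog_map.tsv")
    summary = tq.summarize_by_cog(records, annotations)
    summary.to_csv(ROOT / "cog_summary.tsv", sep="\t", index=False)

    top = (
        summary.groupby("category")["count"].sum().sort_values(ascending=False)
    )
    print("differential calls per COG category (all strains, up+down):")
    for cat, n in top.items():
        print(f"  {n:4d}  {cat}")


if __name__ == "__main__":
    main()
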