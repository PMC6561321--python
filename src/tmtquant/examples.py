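"""Worked example: reported log2 ratios and their prose fold changes.

The package bundles the control-relative log2 abundance ratios reported
for four space-surviving *B. pumilus* SAFR-032 strains (ground-control
normalized; three functional groups: catabolic pathways, competitive
growth advantage, stress response).  These serve as inputs to the
fold-change conversion worked example: each prose statement such as
"2.4-fold lower than the ground control" corresponds to ``2^|log2|``
rounded half-up to one decimal.  Statements about protein pairs (the two
electron transfer flavoprotein subunits, the two fatty-acid β-oxidation
enzymes, Spo0M together with DivIB) average the pair's log2 ratios.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

from .design import STRAIN_CONDITIONS
from .diffabund import fold_change_from_log2

#: Prose fold-change statements tied to the bundled table:
#: name -> (protein GI numbers averaged, strain, reported fold, direction).
PROSE_FOLD_STATEMENTS: dict[str, tuple[tuple[str, ...], str, float, str]] = {
    "odh_dark_space": (("500858752",), "dark_space", 2.0, "down"),
    "dlst_dark_space": (("500858751",), "dark_space", 2.4, "down"),
    "etf_dark_space": (("500859318", "500859319"), "dark_space", 2.6, "down"),
    "fatty_acid_oxidation_dark_space": (
        ("500859322", "500859693"), "dark_space", 2.6, "down",
    ),
    "usp_uv_space": (("754201850",), "uv_space", 2.5, "up"),
    "usp_dark_space": (("754201850",), "dark_space", 1.6, "up"),
    "spo0m_dark_space": (("500859623",), "dark_space", 1.7, "up"),
    "divib_dark_space": (("500858367",), "dark_space", 2.0, "up"),
}


def load_strain_log2_ratios() -> pd.DataFrame:
    """The bundled per-protein log2 ratio table (index: GI number).

    Columns: description, group, one log2-ratio column per strain, COG
    abbreviation, and the reported ANOVA significance flag.
    """
    ref = resources.files("tmtquant.data") / "strain_log2_ratios.tsv"
    with resources.as_file(ref) as path:
        df = pd.read_csv(path, sep="\t", dtype={"gi": str})
    df = df.set_index("gi")
    for strain in STRAIN_CONDITIONS:
        df[strain] = df[strain].astype(float)
    df["significant"] = df["significant"].astype(bool)
    return df


def prose_fold_changes(ndigits: int = 1) -> pd.DataFrame:
    """Recompute every prose fold-change statement from the log2 table.

    Returns one row per statement with the computed magnitude/direction
    next to the reported ones.
    """
    table = load_strain_log2_ratios()
    rows = []
    for name, (gis, strain, reported, direction) in PROSE_FOLD_STATEMENTS.items():
        log2 = float(table.loc[list(gis), strain].mean())
        fc = fold_change_from_log2(log2, ndigits=ndigits)
        rows.append(
            {
                "statement": name,
                "strain": strain,
                "mean_log2": log2,
                "computed_fold": fc.magnitude,
                "computed_direction": fc.direction,
                "reported_fold": reported,
                "reported_direction": direction,
            }
        )
    return pd.DataFrame(rows).set_index("statement")
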