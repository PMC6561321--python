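"""COG functional annotation and per-category up/down summaries.

Annotations are consumed from a user-supplied delimited mapping file
(protein_id → categories); no online retrieval happens here.  A bundled
code table expands the abbreviations used in the study's tables (CTM,
EPC, …) and the standard single-letter COG codes to category names.
Proteins without an annotation fall into "function unknown".
"""

from __future__ import annotations

from typing import Iterable, Mapping

import pandas as pd

from .diffabund import DifferentialRecord

UNKNOWN_CATEGORY = "function unknown"

#: Table-style abbreviations used in the strain comparison tables.
ABBREVIATIONS: dict[str, str] = {
    "CTM": "carbohydrate transport and metabolism",
    "EPC": "energy production and conversion",
    "LTM": "lipid transport and metabolism",
    "SMB": "secondary metabolite biosynthesis, transport and catabolism",
    "CM": "cell motility",
    "STM": "signal transduction mechanisms",
    "CCC": "cell cycle control, cell division, chromosome partitioning",
    "DM": "defense mechanisms",
    "IIT": "inorganic ion transport and metabolism",
    "UN": UNKNOWN_CATEGORY,
    "Transcription": "transcription",
}

#: Standard single-letter COG functional codes.
COG_LETTERS: dict[str, str] = {
    "J": "translation, ribosomal structure and biogenesis",
    "K": "transcription",
    "L": "replication, recombination and repair",
    "D": "cell cycle control, cell division, chromosome partitioning",
    "V": "defense mechanisms",
    "T": "signal transduction mechanisms",
    "M": "cell wall/membrane/envelope biogenesis",
    "N": "cell motility",
    "U": "intracellular trafficking, secretion, and vesicular transport",
    "O": "posttranslational modification, protein turnover, chaperones",
    "C": "energy production and conversion",
    "G": "carbohydrate transport and metabolism",
    "E": "amino acid transport and metabolism",
    "F": "nucleotide transport and metabolism",
    "H": "coenzyme transport and metabolism",
    "I": "lipid transport and metabolism",
    "P": "inorganic ion transport and metabolism",
    "Q": "secondary metabolite biosynthesis, transport and catabolism",
    "R": "general function prediction only",
    "S": UNKNOWN_CATEGORY,
}


class AnnotationError(ValueError):
    pass


def normalize_category(token: str) -> str:
    """Expand an abbreviation or single-letter code to a category name."""
    token = token.strip()
    if token in ABBREVIATIONS:
        return ABBREVIATIONS[token]
    if token in COG_LETTERS:
        return COG_LETTERS[token]
    return token


def read_cog_map(
    path, *, delimiter: str = "\t", category_delimiter: str = ";"
) -> dict[str, frozenset[str]]:
    """Read a protein → COG-categories mapping.

    Two columns (protein_id, categories); multiple categories per protein
    are split on ``category_delimiter``.  Duplicate protein rows are
    merged by set union; malformed lines raise with their line number.
    """
    mapping: dict[str, set[str]] = {}
    with open(path) as fh:
        for line_no, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip() or line.startswith("#"):
                continue
            parts = line.split(delimiter)
            if len(parts) < 2 or not parts[0].strip() or not parts[1].strip():
                raise AnnotationError(f"malformed annotation at line {line_no}")
            pid = parts[0].strip()
            cats = {
                normalize_category(tok)
                for tok in parts[1].split(category_delimiter)
                if tok.strip()
            }
            if not cats:
                raise AnnotationError(f"empty category set at line {line_no}")
            mapping.setdefault(pid, set()).update(cats)
    return {pid: frozenset(cats) for pid, cats in mapping.items()}


def categories_for(
    annotations: Mapping[str, frozenset[str]], protein_id: str
) -> frozenset[str]:
    """Annotated categories, or {"function unknown"} for unannotated ids."""
    return annotations.get(protein_id, frozenset({UNKNOWN_CATEGORY}))


def summarize_by_cog(
    records: Iterable[DifferentialRecord],
    annotations: Mapping[str, frozenset[str]],
) -> pd.DataFrame:
    """Tidy (strain, category, direction, count) table of differential calls.

    A protein with k categories contributes one count to each of the k
    categories (multi-counting, the usual COG bar-chart convention);
    unchanged calls contribute nothing.
    """
    counts: dict[tuple[str, str, str], int] = {}
    for r in records:
        cats = categories_for(annotations, r.protein_id)
        for strain, call in r.call_by_strain.items():
            if call == "unchanged":
                continue
            for cat in cats:
                key = (strain, cat, call)
                counts[key] = counts.get(key, 0) + 1
    rows = [
        {"strain": s, "category": c, "direction": d, "count": n}
        for (s, c, d), n in sorted(counts.items())
    ]
    df = pd.DataFrame(rows, columns=["strain", "category", "direction", "count"])
    df.attrs["multi_counting"] = True
    return df
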