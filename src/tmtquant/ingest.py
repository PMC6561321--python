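"""Reading reporter-ion tables, PSM quality filtering and protein rollup.

The pipeline starts from exported peptide-spectrum-match (PSM) or protein
tables, one row per PSM (or protein) and one intensity column per TMT
channel.  PSMs are screened on co-isolation interference (kept when
≤ 75 %) and mean reporter signal-to-noise (kept when strictly > 10), then
summed per protein.  Proteins are kept for statistics only when they are
quantified in every technical replicate of a plex, technical triplicates
are averaged, and the protein set is intersected across plexes
(biological replicates) before cross-plex normalization.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .design import CHANNELS, PlexDesign


class SchemaError(ValueError):
    """Input table is missing a required column."""


class ParseError(ValueError):
    """Input table contains a malformed value."""


@dataclass
class PSMRecord:
    """One peptide-spectrum match with reporter intensities and QC metrics.

    ``incomplete`` flags records with a blank/missing intensity in any
    channel; such records are retained by the reader (never silently
    dropped) but refuse aggregation.
    """

    protein_id: str
    psm_id: str
    coisolation_pct: float
    mean_reporter_snr: float
    intensities: dict[str, float]
    incomplete: bool = False

    def __post_init__(self) -> None:
        missing = set(CHANNELS) - set(self.intensities)
        if missing:
            raise ValueError(f"missing channels {sorted(missing)}")
        if not self.incomplete:
            for ch, v in self.intensities.items():
                if not math.isfinite(v) or v < 0:
                    raise ValueError(
                        f"non-finite/negative intensity {v!r} in {ch}"
                    )


@dataclass
class ProteinIntensityMatrix:
    """Proteins × channels nonnegative intensities for one plex/tech rep."""

    plex_id: str
    tech_replicate: str
    design: PlexDesign
    data: pd.DataFrame  # index: protein_id, columns: CHANNELS

    def __post_init__(self) -> None:
        self.data = self.data.loc[:, list(CHANNELS)].astype(float)
        if self.data.index.has_duplicates:
            raise ValueError("duplicate protein_ids")
        values = self.data.to_numpy()
        if not np.all(np.isfinite(values)) or (values < 0).any():
            raise ValueError("intensities must be finite and nonnegative")

    def with_data(self, data: pd.DataFrame) -> "ProteinIntensityMatrix":
        return replace(self, data=data)


@dataclass
class FilterStats:
    kept: int
    removed: int


def read_psm_table(
    path, design: PlexDesign, *, delimiter: str = "\t"
) -> list[PSMRecord]:
    """Read a delimited PSM table into records.

    Required columns: ``protein_id``, ``psm_id``, ``coisolation_pct``,
    ``mean_snr`` and the six channel columns.  Blank intensity cells flag
    the record as incomplete; non-numeric cells raise :class:`ParseError`
    with the 1-based file line number.
    """
    raw = pd.read_csv(path, sep=delimiter, dtype=str)
    required = ["protein_id", "psm_id", "coisolation_pct", "mean_snr"]
    for col in required + list(CHANNELS):
        if col not in raw.columns:
            raise SchemaError(f"missing required column {col!r}")

    records: list[PSMRecord] = []
    for i, row in enumerate(raw.itertuples(index=False)):
        row = dict(zip(raw.columns, row))
        line_no = i + 2  # header is line 1
        intensities: dict[str, float] = {}
        incomplete = False
        for ch in CHANNELS:
            cell = row[ch]
            if cell is None or (isinstance(cell, float) and math.isnan(cell)) \
                    or str(cell).strip() == "":
                intensities[ch] = math.nan
                incomplete = True
                continue
            try:
                intensities[ch] = float(cell)
            except ValueError:
                raise ParseError(
                    f"non-numeric intensity {cell!r} in column {ch} "
                    f"at line {line_no}"
                ) from None
        try:
            coiso = float(row["coisolation_pct"])
            snr = float(row["mean_snr"])
        except (TypeError, ValueError):
            raise ParseError(f"non-numeric QC value at line {line_no}") from None
        records.append(
            PSMRecord(
                protein_id=str(row["protein_id"]),
                psm_id=str(row["psm_id"]),
                coisolation_pct=coiso,
                mean_reporter_snr=snr,
                intensities=intensities,
                incomplete=incomplete,
            )
        )
    return records


def filter_psms(
    records: Iterable[PSMRecord],
    max_coisolation: float = 75.0,
    min_snr: float = 10.0,
) -> tuple[list[PSMRecord], FilterStats]:
    """Apply the reporter-ion quality filters.

    A record is kept iff ``coisolation_pct <= max_coisolation`` (inclusive)
    and ``mean_reporter_snr > min_snr`` (strict), preserving input order.
    """
    records = list(records)
    kept = [
        r
        for r in records
        if r.coisolation_pct <= max_coisolation and r.mean_reporter_snr > min_snr
    ]
    return kept, FilterStats(kept=len(kept), removed=len(records) - len(kept))


def drop_incomplete(records: Iterable[PSMRecord]) -> list[PSMRecord]:
    return [r for r in records if not r.incomplete]


def aggregate_to_protein(
    records: Iterable[PSMRecord],
    design: PlexDesign,
    *,
    plex_id: str,
    tech_replicate: str,
) -> ProteinIntensityMatrix:
    """Sum reporter intensities over each protein's surviving PSMs.

    Protein abundance per channel is the total intensity of its detected
    reporter ions; proteins with no surviving records are simply absent.
    Records flagged incomplete must be resolved (dropped) first.
    """
    sums: dict[str, np.ndarray] = {}
    for r in records:
        if r.incomplete:
            raise ValueError(
                f"record {r.psm_id!r} is incomplete; drop or repair it "
                "before aggregation"
            )
        vec = np.array([r.intensities[ch] for ch in CHANNELS], dtype=float)
        if r.protein_id in sums:
            sums[r.protein_id] += vec
        else:
            sums[r.protein_id] = vec.copy()
    data = pd.DataFrame.from_dict(sums, orient="index", columns=list(CHANNELS))
    data.index.name = "protein_id"
    return ProteinIntensityMatrix(
        plex_id=plex_id,
        tech_replicate=tech_replicate,
        design=design,
        data=data.sort_index(),
    )


def filter_complete(
    matrices: Sequence[ProteinIntensityMatrix],
) -> set[str]:
    """Proteins identified and quantified in every technical replicate.

    "Quantified" requires the row to exist with all six channels finite
    and strictly positive; a zero intensity counts as not quantified,
    which protects the downstream log/ratio arithmetic.
    """
    if not matrices:
        raise ValueError("need at least one technical replicate")
    complete: set[str] | None = None
    for m in matrices:
        values = m.data.to_numpy()
        ok = np.isfinite(values).all(axis=1) & (values > 0).all(axis=1)
        present = set(m.data.index[ok])
        complete = present if complete is None else complete & present
    return complete  # type: ignore[return-value]


def average_technical(
    matrices: Sequence[ProteinIntensityMatrix],
    protein_set: Iterable[str],
) -> ProteinIntensityMatrix:
    """Arithmetic mean of technical replicates, restricted to protein_set."""
    proteins = sorted(protein_set)
    if not matrices:
        raise ValueError("need at least one technical replicate")
    stacked = []
    for m in matrices:
        missing = set(proteins) - set(m.data.index)
        if missing:
            raise ValueError(
                f"replicate {m.tech_replicate!r} lacks proteins "
                f"{sorted(missing)[:5]}..."
            )
        stacked.append(m.data.loc[proteins].to_numpy())
    mean = np.mean(stacked, axis=0)
    data = pd.DataFrame(mean, index=pd.Index(proteins, name="protein_id"),
                        columns=list(CHANNELS))
    first = matrices[0]
    return ProteinIntensityMatrix(
        plex_id=first.plex_id,
        tech_replicate="mean",
        design=first.design,
        data=data,
    )


@dataclass
class PlexOverlap:
    per_plex: dict[str, int]
    shared: set[str] = field(repr=False)

    @property
    def overlap_size(self) -> int:
        return len(self.shared)


def intersect_plexes(
    plex_tables: Mapping[str, ProteinIntensityMatrix],
) -> PlexOverlap:
    """Intersection of protein sets across plexes (biological replicates).

    Reports per-plex totals and the overlap size — the structure behind a
    two-set Venn diagram such as 2,146 / 2,225 identified with 1,610 shared.
    """
    if len(plex_tables) < 2:
        raise ValueError("need at least two plexes")
    sets = {pid: set(m.data.index) for pid, m in plex_tables.items()}
    shared: set[str] = set.intersection(*sets.values())
    return PlexOverlap(
        per_plex={pid: len(s) for pid, s in sets.items()}, shared=shared
    )


def write_protein_matrix(matrix: ProteinIntensityMatrix, path) -> None:
    """Write a protein × channel matrix as TSV at full float precision."""
    matrix.data.to_csv(path, sep="\t", float_format="%.17g")


def read_protein_matrix(
    path, design: PlexDesign, *, plex_id: str, tech_replicate: str
) -> ProteinIntensityMatrix:
    data = pd.read_csv(
        path, sep="\t", index_col="protein_id", float_precision="round_trip"
    )
    missing = set(CHANNELS) - set(data.columns)
    if missing:
        raise SchemaError(f"missing channel columns {sorted(missing)}")
    data.index = data.index.astype(str)
    return ProteinIntensityMatrix(
        plex_id=plex_id, tech_replicate=tech_replicate, design=design, data=data
    )
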