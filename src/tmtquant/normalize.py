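"""Three-stage cross-plex normalization: SL → TMM → IRS.

Multi-plex TMT experiments carry three nested nuisance scales:

1. **Sample loading (SL)** — channels within a plex differ in total
   reporter intensity because of pipetting and labeling efficiency; each
   channel is rescaled so its total equals the grand mean of channel
   totals.
2. **TMM (trimmed mean of M-values)** — compositional bias: when a
   minority of proteins truly changes, channel totals are distorted by
   those proteins.  For each channel vs a reference channel we form the
   per-protein log-ratio M and average intensity A (both library-size
   normalized), trim the extremes of both (default 30 % of M, 5 % of A),
   and take the precision-weighted mean of the surviving M values; the
   factor is 2 to that mean, rescaled to geometric mean 1 across
   channels.  The *applied* correction divides each channel by its
   effective size (channel total × factor), again rescaled to geometric
   mean 1 — after SL the totals are equal, so this equals the factor
   itself.
3. **IRS (internal reference scaling)** — the pooled reference channel
   measures the same physical mixture in every plex, so per protein the
   between-plex ratio of reference intensities is pure batch effect; each
   plex's row is multiplied by (geometric-mean reference)/(its own
   reference), after which the reference value is identical across
   plexes.

The weighted trimmed-mean machinery follows the established TMM
estimator (Robinson & Oshlack); intensities are treated as if counts for
the asymptotic-variance weights, with an unweighted switch since
reporter intensities are not true counts.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .design import CHANNELS, PlexDesign
from .diffabund import AbundanceTable
from .ingest import ProteinIntensityMatrix

logger = logging.getLogger(__name__)


class NormalizationError(ValueError):
    pass


def sample_loading_normalize(
    matrix: ProteinIntensityMatrix,
) -> tuple[ProteinIntensityMatrix, pd.Series]:
    """Equalize channel totals to their grand mean.

    Returns the corrected matrix and the per-channel multiplicative
    factors (grand mean / channel total).
    """
    totals = matrix.data.sum(axis=0)
    zero = totals[totals <= 0]
    if len(zero):
        raise NormalizationError(
            f"zero channel total in {list(zero.index)} "
            f"(plex {matrix.plex_id})"
        )
    factors = totals.mean() / totals
    return matrix.with_data(matrix.data * factors), factors


def choose_tmm_reference(data: pd.DataFrame) -> str:
    """Channel whose upper-quartile intensity is nearest the mean of all
    channels' upper quartiles (the standard reference-column convention,
    with quantiles taken on library-size-scaled intensities)."""
    uq = (data / data.sum(axis=0)).quantile(0.75, axis=0)
    return str((uq - uq.mean()).abs().idxmin())


def tmm_factors(
    data: pd.DataFrame,
    ref_channel: str | None = None,
    trim_m: float = 0.30,
    trim_a: float = 0.05,
    *,
    weighted: bool = True,
    min_kept: int = 10,
) -> pd.Series:
    """Per-channel TMM factors, rescaled to geometric mean 1.

    For channel k vs reference r, with channel totals N:
    ``M_p = log2((x_pk/N_k)/(x_pr/N_r))`` and
    ``A_p = ½·log2(x_pk·x_pr/(N_k·N_r))``; proteins outside the central
    ``1−2·trim_m`` of M or ``1−2·trim_a`` of A (rank-based, intersection)
    are discarded and the factor is ``2^(weighted mean of surviving M)``
    with inverse asymptotic-variance weights
    ``1/((N_k−x_pk)/(N_k·x_pk) + (N_r−x_pr)/(N_r·x_pr))``.
    If fewer than ``min_kept`` proteins survive trimming, a warning is
    issued and the untrimmed (weighted) mean is used.
    """
    if ref_channel is None:
        ref_channel = choose_tmm_reference(data)
    if ref_channel not in data.columns:
        raise NormalizationError(f"unknown reference channel {ref_channel!r}")
    N = data.sum(axis=0).astype(float)
    xr = data[ref_channel].to_numpy(dtype=float)
    Nr = float(N[ref_channel])

    raw: dict[str, float] = {}
    for ch in data.columns:
        if ch == ref_channel:
            raw[ch] = 1.0
            continue
        xk = data[ch].to_numpy(dtype=float)
        Nk = float(N[ch])
        ok = (xk > 0) & (xr > 0)
        if ok.sum() == 0:
            raise NormalizationError(
                f"no co-quantified proteins between {ch} and {ref_channel}"
            )
        pk, pr = xk[ok] / Nk, xr[ok] / Nr
        M = np.log2(pk / pr)
        A = 0.5 * np.log2(pk * pr)
        n = len(M)
        lo_m = int(np.floor(n * trim_m)) + 1
        hi_m = n + 1 - lo_m
        lo_a = int(np.floor(n * trim_a)) + 1
        hi_a = n + 1 - lo_a
        rm = rankdata(M, method="average")
        ra = rankdata(A, method="average")
        keep = (rm >= lo_m) & (rm <= hi_m) & (ra >= lo_a) & (ra <= hi_a)
        if keep.sum() < min_kept:
            warnings.warn(
                f"TMM trimming left {int(keep.sum())} proteins for channel "
                f"{ch}; falling back to the untrimmed mean",
                stacklevel=2,
            )
            keep = np.ones(n, dtype=bool)
        if weighted:
            var = (Nk - xk[ok]) / (Nk * xk[ok]) + (Nr - xr[ok]) / (Nr * xr[ok])
            var = np.maximum(var, 1e-24)  # guard exact-total degenerate case
            f = np.sum(M[keep] / var[keep]) / np.sum(1.0 / var[keep])
        else:
            f = float(np.mean(M[keep]))
        raw[ch] = float(2.0**f)

    factors = pd.Series(raw, dtype=float).loc[list(data.columns)]
    return factors / np.exp(np.mean(np.log(factors)))


def tmm_effective_scaling(data: pd.DataFrame, factors: pd.Series) -> pd.Series:
    """The per-channel divisor the TMM stage actually applies.

    Effective channel size = channel total × TMM factor, rescaled to
    geometric mean 1 so the overall intensity scale is preserved.
    """
    eff = data.sum(axis=0) * factors
    return eff / np.exp(np.mean(np.log(eff)))


def tmm_normalize(
    matrix: ProteinIntensityMatrix,
    ref_channel: str | None = None,
    trim_m: float = 0.30,
    trim_a: float = 0.05,
    *,
    weighted: bool = True,
) -> tuple[ProteinIntensityMatrix, pd.Series, pd.Series]:
    """Apply TMM to one plex; returns (matrix, factors, applied scaling)."""
    factors = tmm_factors(
        matrix.data, ref_channel, trim_m, trim_a, weighted=weighted
    )
    scaling = tmm_effective_scaling(matrix.data, factors)
    return matrix.with_data(matrix.data / scaling), factors, scaling


def irs_scale(
    plex_tables: Mapping[str, ProteinIntensityMatrix],
    proteins: Sequence[str] | None = None,
) -> tuple[dict[str, ProteinIntensityMatrix], pd.DataFrame]:
    """Equalize the pooled-reference channel across plexes, per protein.

    The per-protein anchor is the geometric mean of the reference-channel
    intensities over plexes; every channel of plex j is multiplied by
    anchor/reference_j.  Proteins with a nonpositive reference intensity
    in any plex are dropped with a logged reason.
    """
    if len(plex_tables) < 2:
        raise NormalizationError("IRS needs at least two plexes")
    if proteins is None:
        shared = set.intersection(
            *(set(m.data.index) for m in plex_tables.values())
        )
        proteins = sorted(shared)
    proteins = list(proteins)

    refs = pd.DataFrame(
        {
            pid: m.data.loc[proteins, m.design.reference_channel]
            for pid, m in plex_tables.items()
        }
    )
    bad = refs.index[(refs <= 0).any(axis=1)]
    for p in bad:
        logger.info("IRS: dropping %s (nonpositive reference intensity)", p)
    refs = refs.drop(index=bad)
    kept = list(refs.index)

    anchor = np.exp(np.log(refs).mean(axis=1))
    factors = refs.rdiv(anchor, axis=0)  # anchor / ref_j, per protein
    scaled = {
        pid: m.with_data(m.data.loc[kept].mul(factors[pid], axis=0))
        for pid, m in plex_tables.items()
    }
    return scaled, factors


def to_reference_ratios(matrix: ProteinIntensityMatrix) -> pd.DataFrame:
    """Each sample channel divided by the pooled reference channel."""
    ref = matrix.data[matrix.design.reference_channel]
    bad = ref.index[ref <= 0]
    for p in bad:
        logger.info(
            "reference ratio: dropping %s (nonpositive reference)", p
        )
    data = matrix.data.drop(index=bad)
    ref = ref.drop(index=bad)
    return data[list(matrix.design.sample_channels)].div(ref, axis=0)


@dataclass
class NormalizationConfig:
    """Stage selection and TMM tuning for :func:`run_normalization`.

    ``stages`` is an ordered subset of ("sl", "tmm", "irs"); the default
    follows the sentence order SL → TMM → IRS, and ("sl", "irs", "tmm")
    gives the alternative that defers TMM until after batch correction.
    """

    stages: tuple[str, ...] = ("sl", "tmm", "irs")
    tmm_trim_m: float = 0.30
    tmm_trim_a: float = 0.05
    tmm_weighted: bool = True
    tmm_ref_channel: str | None = None

    def __post_init__(self) -> None:
        bad = set(self.stages) - {"sl", "tmm", "irs"}
        if bad:
            raise NormalizationError(f"unknown stages {sorted(bad)}")
        if len(set(self.stages)) != len(self.stages):
            raise NormalizationError("stages must not repeat")


@dataclass
class NormalizationReport:
    """Every factor actually applied, sufficient to replay the pipeline.

    All entries are the multipliers applied to the raw (intersection-
    restricted) matrices, so :meth:`apply` reproduces the output
    bit-for-bit.
    """

    stages_applied: list[str] = field(default_factory=list)
    sl_factors: dict[tuple[str, str], float] = field(default_factory=dict)
    tmm_factors: dict[tuple[str, str], float] = field(default_factory=dict)
    tmm_applied: dict[tuple[str, str], float] = field(default_factory=dict)
    irs_factors: pd.DataFrame | None = None  # index protein, columns plex

    def apply(
        self, plex_tables: Mapping[str, ProteinIntensityMatrix]
    ) -> dict[str, ProteinIntensityMatrix]:
        """Replay the recorded factors against raw plex matrices."""
        proteins = (
            list(self.irs_factors.index)
            if self.irs_factors is not None
            else sorted(
                set.intersection(
                    *(set(m.data.index) for m in plex_tables.values())
                )
            )
        )
        out = {}
        for pid, m in plex_tables.items():
            data = m.data.loc[proteins]
            for stage in self.stages_applied:
                if stage == "sl":
                    f = pd.Series(
                        {ch: self.sl_factors[(pid, ch)] for ch in CHANNELS}
                    )
                    data = data * f
                elif stage == "tmm":
                    s = pd.Series(
                        {ch: self.tmm_applied[(pid, ch)] for ch in CHANNELS}
                    )
                    data = data / s
                elif stage == "irs":
                    assert self.irs_factors is not None
                    data = data.mul(self.irs_factors[pid], axis=0)
            out[pid] = m.with_data(data)
        return out


def run_normalization(
    plex_tables: Mapping[str, ProteinIntensityMatrix],
    config: NormalizationConfig | None = None,
) -> tuple[AbundanceTable, NormalizationReport]:
    """Full cross-plex normalization to a log2 abundance table.

    Restricts to the proteins shared by all plexes, applies the
    configured stages in order, and log2-transforms the sample channels
    into one column per (condition, plex).  The report records every
    factor applied; ``stages=()`` yields log2 of the raw intersection.
    """
    if config is None:
        config = NormalizationConfig()
    shared = sorted(
        set.intersection(*(set(m.data.index) for m in plex_tables.values()))
    )
    if not shared:
        raise NormalizationError("no proteins shared across plexes")
    current: dict[str, ProteinIntensityMatrix] = {
        pid: m.with_data(m.data.loc[shared])
        for pid, m in plex_tables.items()
    }
    report = NormalizationReport()

    for stage in config.stages:
        if stage == "sl":
            for pid in current:
                current[pid], f = sample_loading_normalize(current[pid])
                for ch in CHANNELS:
                    report.sl_factors[(pid, ch)] = float(f[ch])
        elif stage == "tmm":
            for pid in current:
                current[pid], f, applied = tmm_normalize(
                    current[pid],
                    config.tmm_ref_channel,
                    config.tmm_trim_m,
                    config.tmm_trim_a,
                    weighted=config.tmm_weighted,
                )
                for ch in CHANNELS:
                    report.tmm_factors[(pid, ch)] = float(f[ch])
                    report.tmm_applied[(pid, ch)] = float(applied[ch])
        elif stage == "irs":
            current, irs = irs_scale(current)
            report.irs_factors = irs
        report.stages_applied.append(stage)

    columns = {}
    for pid, m in current.items():
        for ch in m.design.sample_channels:
            cond = m.design.channel_to_condition[ch]
            col = m.data[ch]
            if (col <= 0).any():
                bad = list(col.index[col <= 0])
                raise NormalizationError(
                    f"nonpositive intensity before log2 for {bad[:5]}"
                )
            columns[(cond, pid)] = np.log2(col)
    values = pd.DataFrame(columns)
    values.columns = pd.MultiIndex.from_tuples(
        values.columns, names=["condition", "plex"]
    )
    table = AbundanceTable(values=values.sort_index(axis=1))
    return table, report
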