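"""Synthetic TMT reporter-ion data with known ground truth.

Emulates the study design — two six-plex TMT experiments (biological
replicates), each measured in technical triplicate, five sample channels
plus a pooled reference in channel 131 — together with the nuisance
structure a real multi-plex experiment carries:

* per-channel loading/labeling factors (drawn once per channel per plex,
  log-uniform over a configurable range);
* a per-plex batch factor (plexes are separate LC-MS runs on different
  days, so their absolute intensity scales differ);
* compositional bias: a minority of proteins truly changed, the rest null;
* multiplicative log-normal measurement noise, parameterized by its
  coefficient of variation (CV), with unit mean so expectations are exact;
* protein dropout: a protein may be missing from a technical replicate
  entirely (whole row removed), which is what the complete-case filter
  downstream reacts to.

The pooled reference channel is simulated as a *measured* channel: its
expected value is the arithmetic mean of the five samples' true signals
(the equal-mass pool), then it receives its own loading factor and its
own noise draw.

Randomness: a single seed feeds ``numpy.random.SeedSequence``; stage
streams are derived with fixed spawn keys (0 = truth, (1, crc32(plex_id))
= one plex, with the PSM and survival simulators taking explicit seeds),
so each stage is independently reproducible.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .design import (
    CHANNELS,
    CONDITIONS,
    CONTROL_CONDITION,
    STRAIN_CONDITIONS,
    PlexDesign,
    default_design,
)
from .ingest import PSMRecord, ProteinIntensityMatrix
from .assays import SurvivalCurve


class InvalidConfigError(ValueError):
    """Simulation configuration violates its invariants."""


@dataclass(frozen=True)
class SyntheticTruth:
    """Ground truth for one protein: baseline and per-condition fold change.

    Fold changes are linear-scale multipliers relative to the ground
    control, whose own fold change is fixed at 1.
    """

    protein_id: str
    baseline_abundance: float
    fold_change_by_condition: Mapping[str, float]

    def __post_init__(self) -> None:
        if self.baseline_abundance <= 0:
            raise ValueError("baseline_abundance must be > 0")
        if self.fold_change_by_condition.get(CONTROL_CONDITION) != 1.0:
            raise ValueError("control fold change must be 1")
        if any(v <= 0 for v in self.fold_change_by_condition.values()):
            raise ValueError("fold changes must be > 0")

    @property
    def is_differential(self) -> bool:
        return any(
            fc != 1.0
            for cond, fc in self.fold_change_by_condition.items()
            if cond != CONTROL_CONDITION
        )


@dataclass(frozen=True)
class SimulationConfig:
    """Study-shaped simulation parameters.

    Defaults mirror the experiment being emulated: 1000 proteins of which
    100 truly change, fold changes between 1.5× and 4× (random direction),
    loading factors up to 1.5×, a 2× batch factor on the second plex,
    10 % multiplicative noise per technical replicate and 5 % dropout.
    """

    n_proteins: int = 1000
    n_differential: int = 100
    fold_change_range: tuple[float, float] = (1.5, 4.0)
    fold_change_sign: str = "both"  # "both" | "up" | "down"
    differential_conditions: str = "single"  # "single" | "all"
    loading_factor_range: tuple[float, float] = (1 / 1.5, 1.5)
    plex_batch_factors: Mapping[str, float] = field(
        default_factory=lambda: {"plex1": 1.0, "plex2": 2.0}
    )
    baseline_range: tuple[float, float] = (1e4, 1e7)
    n_tech_replicates: int = 3
    noise_cv: float = 0.1
    dropout_rate: float = 0.05
    seed: int = 0

    def validate(self) -> None:
        if self.n_proteins <= 0:
            raise InvalidConfigError("n_proteins must be positive")
        if not 0 <= self.n_differential <= self.n_proteins:
            raise InvalidConfigError(
                "n_differential must be in [0, n_proteins]"
            )
        for name in ("fold_change_range", "loading_factor_range",
                     "baseline_range"):
            lo, hi = getattr(self, name)
            if not (0 < lo <= hi):
                raise InvalidConfigError(f"{name} must satisfy 0 < low <= high")
        if self.fold_change_sign not in ("both", "up", "down"):
            raise InvalidConfigError("fold_change_sign: both|up|down")
        if self.differential_conditions not in ("single", "all"):
            raise InvalidConfigError("differential_conditions: single|all")
        if any(v <= 0 for v in self.plex_batch_factors.values()):
            raise InvalidConfigError("batch factors must be > 0")
        if self.noise_cv < 0:
            raise InvalidConfigError("noise_cv must be >= 0")
        if not 0 <= self.dropout_rate < 1:
            raise InvalidConfigError("dropout_rate must be in [0, 1)")
        if self.n_tech_replicates < 1:
            raise InvalidConfigError("need >= 1 technical replicate")


def _rng(config: SimulationConfig, spawn_key: tuple[int, ...]) -> np.random.Generator:
    return np.random.default_rng(
        np.random.SeedSequence(config.seed, spawn_key=spawn_key)
    )


def _plex_key(plex_id: str) -> tuple[int, int]:
    # crc32 is stable across processes, unlike hash() on str
    return (1, zlib.crc32(plex_id.encode()))


def simulate_truth(config: SimulationConfig) -> list[SyntheticTruth]:
    """Draw per-protein baselines and true fold changes.

    Exactly ``n_differential`` proteins carry a non-unit fold change in at
    least one non-control condition; magnitudes are log-uniform over
    ``fold_change_range`` with direction per ``fold_change_sign``.
    """
    config.validate()
    rng = _rng(config, (0,))
    n = config.n_proteins
    width = len(str(n))
    ids = [f"P{i:0{width}d}" for i in range(1, n + 1)]
    lo, hi = config.baseline_range
    baselines = np.exp(rng.uniform(np.log(lo), np.log(hi), size=n))
    diff_idx = set(rng.choice(n, size=config.n_differential, replace=False))

    truths: list[SyntheticTruth] = []
    flo, fhi = config.fold_change_range
    for i, (pid, base) in enumerate(zip(ids, baselines)):
        fcs = {cond: 1.0 for cond in CONDITIONS}
        if i in diff_idx:
            if config.differential_conditions == "single":
                targets = [STRAIN_CONDITIONS[rng.integers(len(STRAIN_CONDITIONS))]]
            else:
                targets = list(STRAIN_CONDITIONS)
            for cond in targets:
                mag = float(np.exp(rng.uniform(np.log(flo), np.log(fhi))))
                if config.fold_change_sign == "both":
                    up = bool(rng.integers(2))
                else:
                    up = config.fold_change_sign == "up"
                fcs[cond] = mag if up else 1.0 / mag
        truths.append(
            SyntheticTruth(
                protein_id=pid,
                baseline_abundance=float(base),
                fold_change_by_condition=fcs,
            )
        )
    return truths


def expected_intensities(
    truth: Sequence[SyntheticTruth],
    design: PlexDesign,
    loading_factors: Mapping[str, float],
    batch_factor: float,
) -> pd.DataFrame:
    """Noise-free expected matrix: baseline × fold change × loading × batch.

    The reference channel's true signal is the arithmetic mean of the five
    samples' (baseline × fold change), before its own loading factor.
    """
    rows = {}
    for t in truth:
        true_signal = {
            ch: t.baseline_abundance
            * t.fold_change_by_condition[design.channel_to_condition[ch]]
            for ch in design.sample_channels
        }
        ref = float(np.mean(list(true_signal.values())))
        true_signal[design.reference_channel] = ref
        rows[t.protein_id] = [
            true_signal[ch] * loading_factors[ch] * batch_factor
            for ch in CHANNELS
        ]
    df = pd.DataFrame.from_dict(rows, orient="index", columns=list(CHANNELS))
    df.index.name = "protein_id"
    return df


def _lognormal_noise(
    rng: np.random.Generator, cv: float, shape: tuple[int, ...]
) -> np.ndarray:
    if cv == 0:
        return np.ones(shape)
    sigma2 = np.log1p(cv**2)
    sigma = np.sqrt(sigma2)
    # unit-mean log-normal: E[exp(N(-sigma^2/2, sigma^2))] = 1
    return np.exp(rng.normal(-sigma2 / 2, sigma, size=shape))


def simulate_plex(
    truth: Sequence[SyntheticTruth],
    plex_id: str,
    config: SimulationConfig,
) -> list[ProteinIntensityMatrix]:
    """Simulate all technical replicates of one plex.

    Returns ``n_tech_replicates`` matrices sharing the plex's loading and
    batch factors; each replicate gets independent noise and dropout.
    """
    config.validate()
    if not truth:
        raise ValueError("truth must be nonempty")
    rng = _rng(config, _plex_key(plex_id))
    design = default_design(plex_id)
    llo, lhi = config.loading_factor_range
    loading = {
        ch: float(np.exp(rng.uniform(np.log(llo), np.log(lhi))))
        for ch in CHANNELS
    }
    batch = float(config.plex_batch_factors.get(plex_id, 1.0))
    expected = expected_intensities(truth, design, loading, batch)

    matrices = []
    for rep in range(1, config.n_tech_replicates + 1):
        noise = _lognormal_noise(rng, config.noise_cv, expected.shape)
        observed = expected * noise
        keep = rng.random(len(observed)) >= config.dropout_rate
        matrices.append(
            ProteinIntensityMatrix(
                plex_id=plex_id,
                tech_replicate=f"rep{rep}",
                design=design,
                data=observed.loc[keep],
            )
        )
    return matrices


def _draw(dist, rng: np.random.Generator, size: int) -> np.ndarray:
    """A QC-metric distribution: scalar constant or rv with ``.rvs``."""
    if np.isscalar(dist):
        return np.full(size, float(dist))
    return np.asarray(dist.rvs(size=size, random_state=rng), dtype=float)


def simulate_psm_table(
    matrix: ProteinIntensityMatrix,
    psms_per_protein: int,
    coisolation_distribution,
    snr_distribution,
    seed: int,
) -> list[PSMRecord]:
    """Explode a protein matrix into PSM records with QC covariates.

    Each protein row is split over ``psms_per_protein`` records by
    Dirichlet weights (a single PSM reproduces the row exactly), so that
    summing a protein's records recovers its row.  Co-isolation % and mean
    reporter S/N are drawn from the given distributions — scalar constants
    or scipy frozen distributions — independently of the intensities.
    """
    if psms_per_protein < 1:
        raise InvalidConfigError("psms_per_protein must be >= 1")
    rng = np.random.default_rng(seed)
    records: list[PSMRecord] = []
    n = len(matrix.data)
    coiso = _draw(coisolation_distribution, rng, n * psms_per_protein)
    snr = _draw(snr_distribution, rng, n * psms_per_protein)
    k = 0
    for pid, row in matrix.data.iterrows():
        if psms_per_protein == 1:
            weights = np.ones(1)
        else:
            weights = rng.dirichlet(np.full(psms_per_protein, 5.0))
        for j, w in enumerate(weights, start=1):
            records.append(
                PSMRecord(
                    protein_id=str(pid),
                    psm_id=f"{pid}_psm{j}",
                    coisolation_pct=float(coiso[k]),
                    mean_reporter_snr=float(snr[k]),
                    intensities={ch: float(row[ch] * w) for ch in CHANNELS},
                )
            )
            k += 1
    return records


def simulate_survival_counts(
    n0: float,
    doses: Iterable[float],
    log_linear_slope: float,
    seed: int,
    *,
    strain: str = "synthetic",
    detection_limit: float = 10.0,
) -> SurvivalCurve:
    """Poisson CFU counts under log-linear UV kill kinetics.

    Expected CFU/ml at dose d is ``n0 × 10^(−slope·d)``; observed counts
    are Poisson draws (zeros allowed).  When dose 0 is included, the
    curve's n0 is the observed dose-0 count so that the curve's own
    invariant (n0 = cfu at dose 0) holds for downstream fraction
    arithmetic.
    """
    doses = np.asarray(list(doses), dtype=float)
    if n0 <= 0:
        raise ValueError("n0 must be > 0")
    if (doses < 0).any():
        raise ValueError("doses must be nonnegative")
    rng = np.random.default_rng(seed)
    expected = n0 * 10.0 ** (-log_linear_slope * doses)
    counts = rng.poisson(expected).astype(float)
    observed_n0 = float(counts[doses == 0][0]) if (doses == 0).any() else float(n0)
    if observed_n0 <= 0:
        # a zero draw at dose 0 would make fractions undefined; fall back
        observed_n0 = float(n0)
        if (doses == 0).any():
            counts[doses == 0] = observed_n0
    return SurvivalCurve(
        strain=strain,
        doses=tuple(float(d) for d in doses),
        cfu_counts=tuple(float(c) for c in counts),
        n0=observed_n0,
        detection_limit=detection_limit,
    )


def write_truth_table(truth: Sequence[SyntheticTruth], path) -> None:
    """Tidy TSV: protein_id, condition, fold_change."""
    rows = [
        (t.protein_id, cond, fc)
        for t in truth
        for cond, fc in t.fold_change_by_condition.items()
    ]
    pd.DataFrame(rows, columns=["protein_id", "condition", "fold_change"]).to_csv(
        path, sep="\t", index=False, float_format="%.17g"
    )


def write_psm_table(records: Sequence[PSMRecord], path) -> None:
    rows = []
    for r in records:
        row = {
            "protein_id": r.protein_id,
            "psm_id": r.psm_id,
            "coisolation_pct": r.coisolation_pct,
            "mean_snr": r.mean_reporter_snr,
        }
        row.update({ch: r.intensities[ch] for ch in CHANNELS})
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False, float_format="%.17g")
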