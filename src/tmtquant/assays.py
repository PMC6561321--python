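"""UV survival kinetics and enzyme-assay statistics.

Survival is summarized from colony counts: the surviving fraction at
dose d is CFU(d)/N0 and the log reduction is log10(N0/CFU(d)).  Plates
with zero colonies are reported as censored bounds at the detection
limit rather than infinite reductions.  Enzyme-activity and ATP endpoint
comparisons use one-way ANOVA with Tukey's HSD (Tukey–Kramer for unequal
group sizes), with the significance tiers ≤0.05 / ≤0.005 / ≤0.0001 used
for figure-style stars.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats


@dataclass(frozen=True)
class SurvivalCurve:
    """CFU counts over UV254 doses for one strain."""

    strain: str
    doses: tuple[float, ...]  # J/m^2, strictly increasing
    cfu_counts: tuple[float, ...]  # CFU/ml; zero allowed
    n0: float  # CFU/ml at dose 0
    detection_limit: float = 10.0  # CFU/ml

    def __post_init__(self) -> None:
        doses = np.asarray(self.doses, dtype=float)
        counts = np.asarray(self.cfu_counts, dtype=float)
        if len(doses) != len(counts):
            raise ValueError("doses and counts differ in length")
        if (doses < 0).any():
            raise ValueError("doses must be nonnegative")
        if not np.all(np.diff(doses) > 0):
            raise ValueError("doses must be strictly increasing")
        if (counts < 0).any():
            raise ValueError("CFU counts must be nonnegative")
        if self.n0 <= 0:
            raise ValueError("n0 must be > 0")
        if (doses == 0).any() and counts[doses == 0][0] != self.n0:
            raise ValueError("n0 must equal the CFU count at dose 0")

    def cfu_at(self, dose: float) -> float:
        doses = np.asarray(self.doses)
        idx = np.nonzero(doses == dose)[0]
        if len(idx) == 0:
            raise KeyError(f"dose {dose} not measured")
        return float(self.cfu_counts[idx[0]])


def average_dilution_series(cfu_per_ml: Sequence[float]) -> float:
    """Arithmetic mean of back-calculated CFU/ml from replicate platings."""
    values = np.asarray(cfu_per_ml, dtype=float)
    if (values < 0).any():
        raise ValueError("CFU/ml must be nonnegative")
    return float(values.mean())


def survival_fraction(curve: SurvivalCurve) -> pd.DataFrame:
    """Surviving fraction per dose, with censoring at the detection limit.

    Zero counts are reported as ``fraction = detection_limit/n0`` with
    ``censored = True`` (read "< detection_limit/n0").
    """
    doses = np.asarray(curve.doses, dtype=float)
    counts = np.asarray(curve.cfu_counts, dtype=float)
    censored = counts == 0
    fraction = np.where(censored, curve.detection_limit, counts) / curve.n0
    return pd.DataFrame(
        {"dose": doses, "fraction": fraction, "censored": censored}
    )


@dataclass(frozen=True)
class LogReduction:
    value: float  # log10(n0/cfu); a lower bound when censored
    censored: bool


def log_reduction(curve: SurvivalCurve, dose: float) -> LogReduction:
    """log10 kill magnitude at a measured dose.

    Finite when colonies were observed; when the count is zero the value
    is the lower bound log10(n0/detection_limit) with ``censored=True``.
    """
    cfu = curve.cfu_at(dose)
    if cfu == 0:
        return LogReduction(
            value=float(np.log10(curve.n0 / curve.detection_limit)),
            censored=True,
        )
    return LogReduction(value=float(np.log10(curve.n0 / cfu)), censored=False)


def significance_tier(p: float) -> str:
    """Figure-style stars: * ≤0.05, ** ≤0.005, **** ≤0.0001."""
    if p <= 0.0001:
        return "****"
    if p <= 0.005:
        return "**"
    if p <= 0.05:
        return "*"
    return ""


@dataclass
class AssayStats:
    overall_p: float
    pairwise: pd.DataFrame  # columns: group_a, group_b, p_adj, tier
    degenerate: bool = False

    def versus(self, control: str) -> pd.DataFrame:
        mask = (self.pairwise["group_a"] == control) | (
            self.pairwise["group_b"] == control
        )
        return self.pairwise[mask].reset_index(drop=True)


def anova_tukey(
    groups: Mapping[str, Sequence[float]], alpha: float = 0.05
) -> AssayStats:
    """One-way ANOVA with Tukey's HSD over replicate assay measurements.

    Requires ≥2 groups with ≥2 replicates each.  Pairwise p-values come
    from the studentized-range distribution on the pooled within-group
    variance (Tukey–Kramer when group sizes differ).  A zero pooled
    variance is flagged degenerate: overall p is 1 when all group means
    agree, else 0.
    """
    names = list(groups)
    if len(names) < 2:
        raise ValueError("need at least two groups")
    arrays = [np.asarray(groups[n], dtype=float) for n in names]
    if min(len(a) for a in arrays) < 2:
        raise ValueError("need at least two replicates per group")

    pooled_var = sum(((a - a.mean()) ** 2).sum() for a in arrays) / (
        sum(len(a) for a in arrays) - len(arrays)
    )
    if pooled_var == 0:
        means = [a.mean() for a in arrays]
        same = np.allclose(means, means[0])
        pairs = [
            {
                "group_a": a,
                "group_b": b,
                "p_adj": 1.0 if same else 0.0,
                "tier": "" if same else "****",
            }
            for i, a in enumerate(names)
            for b in names[i + 1:]
        ]
        return AssayStats(
            overall_p=1.0 if same else 0.0,
            pairwise=pd.DataFrame(pairs),
            degenerate=True,
        )

    overall = stats.f_oneway(*arrays)
    hsd = stats.tukey_hsd(*arrays)
    pairs = []
    for i, a in enumerate(names):
        for j in range(i + 1, len(names)):
            p = float(hsd.pvalue[i, j])
            pairs.append(
                {
                    "group_a": a,
                    "group_b": names[j],
                    "p_adj": p,
                    "tier": significance_tier(p),
                }
            )
    return AssayStats(
        overall_p=float(overall.pvalue), pairwise=pd.DataFrame(pairs)
    )
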