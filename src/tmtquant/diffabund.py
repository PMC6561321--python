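"""Differential abundance: control-relative ratios, ANOVA, fold calls.

Protein abundances are compared to the unexposed ground-control strain:
per strain, the log2 ratio is the across-plex mean of (strain − control)
log2 abundance.  A one-way fixed-effects ANOVA across the five strains
(plexes as replicates, technical replicates already averaged) flags
significance at raw P ≤ 0.05 — deliberately uncorrected, with a
Benjamini–Hochberg column emitted alongside for transparency.  Up/down
calls use a ±1.5-fold threshold on the linear scale (|log2 ratio| ≥
log2 1.5 ≈ 0.585, inclusive), independent of significance.  Strain
profiles are summarized by agglomerative hierarchical clustering.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import scipy.cluster.hierarchy as sch
from scipy import stats
from scipy.spatial.distance import pdist

from .design import CONTROL_CONDITION


@dataclass
class AbundanceTable:
    """Log2 abundances, one column per (condition, plex).

    ``values`` has protein ids as index and a two-level column index
    (condition, plex); every condition must be present in every plex.
    """

    values: pd.DataFrame
    control_condition: str = CONTROL_CONDITION

    def __post_init__(self) -> None:
        if not isinstance(self.values.columns, pd.MultiIndex):
            raise ValueError("columns must be a (condition, plex) MultiIndex")
        if not np.all(np.isfinite(self.values.to_numpy())):
            raise ValueError("abundances must be finite")
        conds = self.values.columns.get_level_values(0)
        if self.control_condition not in set(conds):
            raise ValueError(
                f"control condition {self.control_condition!r} absent"
            )
        per_plex = {
            plex: set(
                self.values.columns[
                    self.values.columns.get_level_values(1) == plex
                ].get_level_values(0)
            )
            for plex in set(self.values.columns.get_level_values(1))
        }
        expected = set(conds)
        for plex, have in per_plex.items():
            if have != expected:
                raise ValueError(f"plex {plex!r} lacks conditions "
                                 f"{sorted(expected - have)}")

    @property
    def conditions(self) -> tuple[str, ...]:
        seen: list[str] = []
        for c in self.values.columns.get_level_values(0):
            if c not in seen:
                seen.append(c)
        return tuple(seen)

    @property
    def plexes(self) -> tuple[str, ...]:
        seen: list[str] = []
        for p in self.values.columns.get_level_values(1):
            if p not in seen:
                seen.append(p)
        return tuple(seen)


def control_relative_log2(table: AbundanceTable) -> pd.DataFrame:
    """Per-protein, per-strain log2 ratio to the ground control.

    For strain s: mean over plexes of (log2 abundance of s − log2
    abundance of control, within the same plex).  The control's own ratio
    is identically zero and is omitted from the returned columns.
    """
    control = table.values.xs(table.control_condition, axis=1, level=0)
    out = {}
    for cond in table.conditions:
        if cond == table.control_condition:
            continue
        strain = table.values.xs(cond, axis=1, level=0)
        out[cond] = (strain - control[strain.columns]).mean(axis=1)
    return pd.DataFrame(out)


@dataclass(frozen=True)
class FoldChange:
    magnitude: float  # linear fold, >= 1
    direction: str  # "up" | "down" | "none"


def _round_half_up(x: float, ndigits: int) -> float:
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))


def fold_change_from_log2(x: float, ndigits: int | None = None) -> FoldChange:
    """Convert a log2 ratio to a reporting-style linear fold change.

    Magnitude is ``2^|x|`` (optionally rounded half-up to ``ndigits``
    decimals, the convention behind statements like "2.4-fold lower");
    direction is the sign of x.
    """
    if not np.isfinite(x):
        raise ValueError("log2 ratio must be finite")
    mag = float(2.0 ** abs(x))
    if ndigits is not None:
        mag = _round_half_up(mag, ndigits)
    direction = "up" if x > 0 else "down" if x < 0 else "none"
    return FoldChange(magnitude=mag, direction=direction)


def anova_per_protein(
    table: AbundanceTable, alpha: float = 0.05
) -> pd.DataFrame:
    """Classical one-way fixed-effects ANOVA across strains, per protein.

    Groups are the conditions (control included); observations are the
    plexes.  Returns columns ``p_value``, ``f_stat``, ``significant``
    (p ≤ alpha), ``bh_q`` (Benjamini–Hochberg, reported only) and
    ``degenerate`` ("constant" when all observations are identical,
    p = 1 by convention; "zero_residual" when within-group variance is
    zero with unequal means, p → 0).
    """
    groups = [
        table.values.xs(cond, axis=1, level=0).to_numpy()
        for cond in table.conditions
    ]
    k = len(groups)
    if k < 2:
        raise ValueError("need at least two groups")
    ns = [g.shape[1] for g in groups]
    if min(ns) < 2:
        raise ValueError("need at least two observations per group")
    n_total = sum(ns)
    df_between, df_within = k - 1, n_total - k
    if df_within < 1:
        raise ValueError("no residual degrees of freedom")

    grand = np.hstack(groups)
    grand_mean = grand.mean(axis=1)
    means = [g.mean(axis=1) for g in groups]
    ssb = sum(n * (m - grand_mean) ** 2 for n, m in zip(ns, means))
    ssw = sum(((g - m[:, None]) ** 2).sum(axis=1) for g, m in zip(groups, means))

    with np.errstate(divide="ignore", invalid="ignore"):
        f = (ssb / df_between) / (ssw / df_within)
    p = stats.f.sf(f, df_between, df_within)

    scale = np.maximum(np.abs(grand).max(axis=1), 1.0)
    tol = 1e-12
    constant = (ssb <= tol * scale**2) & (ssw <= tol * scale**2)
    zero_resid = (ssw <= tol * scale**2) & ~constant
    p = np.where(constant, 1.0, np.where(zero_resid, 0.0, p))
    f = np.where(constant, 0.0, f)

    flag = np.where(
        constant, "constant", np.where(zero_resid, "zero_residual", "")
    )
    bh = stats.false_discovery_control(np.clip(p, 0.0, 1.0), method="bh")
    return pd.DataFrame(
        {
            "p_value": p,
            "f_stat": f,
            "significant": p <= alpha,
            "bh_q": bh,
            "degenerate": flag,
        },
        index=table.values.index,
    )


@dataclass
class DifferentialRecord:
    """Per-protein differential-abundance summary.

    A strain call is "up" when its log2 ratio ≥ +log2(threshold), "down"
    when ≤ −log2(threshold), else "unchanged"; ``significant`` reflects
    the ANOVA p-value alone and is independent of the calls.
    """

    protein_id: str
    log2_ratio_by_strain: dict[str, float]
    anova_p: float
    call_by_strain: dict[str, str]
    significant: bool

    @property
    def differential_strains(self) -> tuple[str, ...]:
        return tuple(
            s for s, c in self.call_by_strain.items() if c != "unchanged"
        )


def classify(
    ratios: pd.DataFrame,
    pvalues: pd.Series,
    threshold: float = 1.5,
    alpha: float = 0.05,
) -> list[DifferentialRecord]:
    """±threshold-fold up/down calls plus an ANOVA significance flag.

    ``ratios`` is proteins × strains (control-relative log2); the
    comparison is inclusive: |log2 ratio| ≥ log2(threshold).
    """
    if threshold <= 1:
        raise ValueError("threshold must be > 1")
    cut = np.log2(threshold)
    records = []
    for pid, row in ratios.iterrows():
        calls = {
            strain: (
                "up" if row[strain] >= cut
                else "down" if row[strain] <= -cut
                else "unchanged"
            )
            for strain in ratios.columns
        }
        p = float(pvalues.loc[pid])
        records.append(
            DifferentialRecord(
                protein_id=str(pid),
                log2_ratio_by_strain={s: float(row[s]) for s in ratios.columns},
                anova_p=p,
                call_by_strain=calls,
                significant=p <= alpha,
            )
        )
    return records


@dataclass
class DifferentialCounts:
    per_strain_up: dict[str, int]
    per_strain_down: dict[str, int]
    per_strain_total: dict[str, int]
    per_strain_unique: dict[str, int]
    union_count: int
    multi_strain_count: int
    significant_count: int

    def consistent(self) -> bool:
        """union = Σ uniques + proteins differential in ≥ 2 strains."""
        return self.union_count == (
            sum(self.per_strain_unique.values()) + self.multi_strain_count
        )


def count_differential(
    records: Iterable[DifferentialRecord],
) -> DifferentialCounts:
    """Per-strain up/down/total counts, unique counts and union.

    "Unique" means differential in exactly that one strain;
    ``significant_count`` is the size of the ANOVA-significant subset of
    the ≥1-strain union (the structure behind "301 proteins … 70 of
    these had P ≤ 0.05").
    """
    records = list(records)
    strains: list[str] = []
    for r in records:
        for s in r.call_by_strain:
            if s not in strains:
                strains.append(s)
    up = {s: 0 for s in strains}
    down = {s: 0 for s in strains}
    total = {s: 0 for s in strains}
    unique = {s: 0 for s in strains}
    union = multi = signif = 0
    for r in records:
        hits = r.differential_strains
        for s in hits:
            total[s] += 1
            if r.call_by_strain[s] == "up":
                up[s] += 1
            else:
                down[s] += 1
        if hits:
            union += 1
            if len(hits) == 1:
                unique[hits[0]] += 1
            else:
                multi += 1
            if r.significant:
                signif += 1
    return DifferentialCounts(
        per_strain_up=up,
        per_strain_down=down,
        per_strain_total=total,
        per_strain_unique=unique,
        union_count=union,
        multi_strain_count=multi,
        significant_count=signif,
    )


@dataclass
class ClusterResult:
    labels: list[str]
    linkage: np.ndarray
    leaf_order: list[str]
    newick: str


def _linkage_to_newick(linkage: np.ndarray, labels: Sequence[str]) -> str:
    tree = sch.to_tree(linkage)

    def render(node) -> str:
        if node.is_leaf():
            # quote labels so underscores survive newick round-trips
            return f"'{labels[node.id]}'"
        left, right = render(node.get_left()), render(node.get_right())
        half = node.dist / 2.0
        return f"({left}:{half:.6g},{right}:{half:.6g})"

    return render(tree) + ";"


def hierarchical_cluster(
    ratios: pd.DataFrame,
    metric: str = "euclidean",
    method: str = "average",
) -> ClusterResult:
    """Agglomerative clustering of strain columns of a log2-ratio table.

    Defaults: Euclidean distance, average linkage.  The tree is returned
    as a scipy linkage matrix, a dendrogram leaf order, and a newick
    string (ultrametric heights = half the merge distance).
    """
    labels = [str(c) for c in ratios.columns]
    if len(labels) < 2:
        raise ValueError("need at least two columns to cluster")
    X = ratios.to_numpy().T
    dist = pdist(X, metric=metric)
    linkage = sch.linkage(dist, method=method)
    order = [labels[i] for i in sch.leaves_list(linkage)]
    return ClusterResult(
        labels=labels,
        linkage=linkage,
        leaf_order=order,
        newick=_linkage_to_newick(linkage, labels),
    )


def records_to_frame(records: Sequence[DifferentialRecord]) -> pd.DataFrame:
    """Tidy per-protein table mirroring the published layout: one log2
    column per strain, the ANOVA p-value and a significance star."""
    strains = list(records[0].log2_ratio_by_strain) if records else []
    rows = []
    for r in records:
        row: dict[str, object] = {"protein_id": r.protein_id}
        for s in strains:
            row[s] = r.log2_ratio_by_strain[s]
        row["anova_p"] = r.anova_p
        row["star"] = "*" if r.significant else ""
        rows.append(row)
    return pd.DataFrame(rows)
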