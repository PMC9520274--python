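"""Quantification and statistics for sonoporation experiments.

Measurements are percentages in [0, 100]: count-based fluorescent-cell
fractions (dye-positive cells over nucleus-stained total), area-based
fractions (green confluence over phase confluence), or viability relative
to the sham group. Treatment groups are compared by one-way ANOVA followed
by Tukey's multiple-comparison test, and uptake is summarized as fold
change versus sham.
"""

from __future__ import annotations

import itertools
import json
from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "GROUP_LABELS",
    "GROUP_PNP_KPA",
    "GroupMeasurements",
    "ExperimentTable",
    "UptakeSummary",
    "AnovaTukeyResult",
    "fraction_fluorescent_count",
    "fraction_fluorescent_area",
    "fold_uptake",
    "viability_percent",
    "one_way_anova",
    "tukey_hsd",
    "dose_response_summary",
    "significance_stars",
    "analyze_table",
]

# Canonical treatment groups; tmb_us_<n> means targeted microbubbles plus
# ultrasound at a peak negative pressure of <n> kPa.
GROUP_PNP_KPA: dict[str, Optional[float]] = {
    "sham": None,
    "us_only": None,
    "tmb_only": None,
    "tmb_us_100": 100.0,
    "tmb_us_200": 200.0,
    "tmb_us_300": 300.0,
    "tmb_us_500": 500.0,
    "tmb_us_800": 800.0,
}
GROUP_LABELS = tuple(GROUP_PNP_KPA)

MOLECULES = ("7aad_1.2kDa", "fitc_4kDa", "fitc_20kDa", "fitc_70kDa")
METRICS = ("count_fraction", "area_fraction", "viability_percent")


@dataclass(frozen=True)
class GroupMeasurements:
    """Replicate-level percentage values for one treatment group."""

    group_label: str
    replicate_values: np.ndarray  # %, each in [0, 100] (viability may exceed)

    def __post_init__(self) -> None:
        values = np.asarray(self.replicate_values, dtype=float)
        object.__setattr__(self, "replicate_values", values)
        if self.group_label not in GROUP_PNP_KPA:
            raise ValueError(f"unknown group label {self.group_label!r}")
        if values.size < 1:
            raise ValueError("need at least one replicate")

    @property
    def n_replicates(self) -> int:
        return int(self.replicate_values.size)

    @property
    def mean(self) -> float:
        return float(np.mean(self.replicate_values))

    @property
    def sd(self) -> float:
        return float(np.std(self.replicate_values, ddof=1)) if self.n_replicates > 1 else 0.0

    @property
    def pnp_kpa(self) -> Optional[float]:
        return GROUP_PNP_KPA[self.group_label]


@dataclass(frozen=True)
class ExperimentTable:
    """All groups of one experiment (one molecule, one metric, one timepoint)."""

    molecule: str
    metric: str
    timepoint_h: float
    groups: tuple[GroupMeasurements, ...]

    def __post_init__(self) -> None:
        if self.metric not in METRICS:
            raise ValueError(f"unknown metric {self.metric!r}")
        object.__setattr__(self, "groups", tuple(self.groups))
        labels = [g.group_label for g in self.groups]
        if labels.count("sham") != 1:
            raise ValueError("exactly one sham group is required")
        if len(set(labels)) != len(labels):
            raise ValueError("duplicate group labels")

    @property
    def sham(self) -> GroupMeasurements:
        return next(g for g in self.groups if g.group_label == "sham")

    def group(self, label: str) -> GroupMeasurements:
        for g in self.groups:
            if g.group_label == label:
                return g
        raise KeyError(label)

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {
                "molecule": self.molecule,
                "metric": self.metric,
                "timepoint_h": self.timepoint_h,
                "group": g.group_label,
                "replicate": i + 1,
                "value": v,
            }
            for g in self.groups
            for i, v in enumerate(g.replicate_values)
        ]
        return pd.DataFrame(rows)

    def to_csv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_frame(cls, frame: pd.DataFrame) -> "ExperimentTable":
        keys = frame[["molecule", "metric", "timepoint_h"]].drop_duplicates()
        if len(keys) != 1:
            raise ValueError("frame must contain exactly one experiment")
        molecule, metric, timepoint = keys.iloc[0]
        groups = tuple(
            GroupMeasurements(label, sub.sort_values("replicate")["value"].to_numpy())
            for label, sub in frame.groupby("group", sort=False)
        )
        return cls(molecule=molecule, metric=metric, timepoint_h=float(timepoint),
                   groups=groups)

    @classmethod
    def from_csv(cls, path: str | Path) -> "ExperimentTable":
        return cls.from_frame(pd.read_csv(path))


@dataclass(frozen=True)
class UptakeSummary:
    molecule: str
    metric: str
    timepoint_h: float
    group_means: dict[str, float]
    group_sds: dict[str, float]
    fold_vs_sham: dict[str, float]
    optimal_pnp_kpa: float


@dataclass(frozen=True)
class AnovaTukeyResult:
    F_statistic: float
    p_value: float
    pairwise: tuple[tuple[str, str, float, float], ...]  # (a, b, mean diff, adj p)


# ---------------------------------------------------------------------------
# Elementary fractions


def _ratio_percent(numerator: float, denominator: float, what: str) -> float:
    if denominator <= 0:
        raise ValueError(f"{what}: denominator must be > 0")
    if numerator < 0:
        raise ValueError(f"{what}: numerator must be >= 0")
    if numerator > denominator:
        raise ValueError(f"{what}: numerator exceeds denominator")
    return 100.0 * numerator / denominator


def fraction_fluorescent_count(stained: float, total: float) -> float:
    """Percentage of dye-positive cells among all (nucleus-stained) cells."""
    return _ratio_percent(stained, total, "fraction_fluorescent_count")


def fraction_fluorescent_area(green_area: float, phase_area: float) -> float:
    """Green confluence normalized by phase (total cell) confluence, in %."""
    return _ratio_percent(green_area, phase_area, "fraction_fluorescent_area")


def viability_percent(group_count: float, sham_count: float) -> float:
    """Remaining cells as a percentage of the sham group (may exceed 100)."""
    if sham_count <= 0:
        raise ValueError("sham_count must be > 0")
    if group_count < 0:
        raise ValueError("group_count must be >= 0")
    return 100.0 * group_count / sham_count


def fold_uptake(
    group: GroupMeasurements | float,
    sham: GroupMeasurements | float,
    mode: str = "mean-ratio",
) -> float | tuple[float, float]:
    """Fold change of a treatment group relative to sham.

    ``mean-ratio`` (default) returns group_mean / sham_mean. ``replicate``
    pairs replicates by index, forms per-replicate ratios, and returns
    their (mean, sd); the two conventions differ slightly whenever the
    replicate values vary.
    """
    g_mean = group.mean if isinstance(group, GroupMeasurements) else float(group)
    s_mean = sham.mean if isinstance(sham, GroupMeasurements) else float(sham)
    if s_mean <= 0:
        raise ValueError("sham mean must be > 0 for a fold change")
    if mode == "mean-ratio":
        return g_mean / s_mean
    if mode == "replicate":
        if not isinstance(group, GroupMeasurements) or not isinstance(
            sham, GroupMeasurements
        ):
            raise TypeError("replicate mode needs GroupMeasurements inputs")
        if group.n_replicates != sham.n_replicates:
            raise ValueError("replicate mode requires equal replicate counts")
        if np.any(sham.replicate_values <= 0):
            raise ValueError("replicate mode requires positive sham replicates")
        ratios = group.replicate_values / sham.replicate_values
        sd = float(np.std(ratios, ddof=1)) if ratios.size > 1 else 0.0
        return float(np.mean(ratios)), sd
    raise ValueError(f"unknown fold mode {mode!r}")


# ---------------------------------------------------------------------------
# ANOVA + Tukey


def one_way_anova(groups: Sequence[GroupMeasurements]) -> tuple[float, float]:
    """One-way fixed-effects ANOVA from the definitional sums of squares.

    Returns (F, p) with F = MS_between / MS_within and p from the upper
    tail of the F distribution. All-constant input (zero within-group
    variance everywhere) is degenerate and raises.
    """
    if len(groups) < 2:
        raise ValueError("need at least two groups")
    values = [np.asarray(g.replicate_values, dtype=float) for g in groups]
    if any(v.size < 2 for v in values):
        raise ValueError("each group needs at least two replicates")
    k = len(values)
    n_total = sum(v.size for v in values)
    grand = np.concatenate(values).mean()
    ss_between = sum(v.size * (v.mean() - grand) ** 2 for v in values)
    ss_within = sum(((v - v.mean()) ** 2).sum() for v in values)
    df_between = k - 1
    df_within = n_total - k
    if ss_within == 0.0:
        raise ValueError("degenerate input: zero within-group variance")
    f_stat = (ss_between / df_between) / (ss_within / df_within)
    p = float(sps.f.sf(f_stat, df_between, df_within))
    return float(f_stat), p


def tukey_hsd(
    groups: Sequence[GroupMeasurements], alpha: float = 0.05
) -> AnovaTukeyResult:
    """Tukey's multiple-comparison test over all unordered group pairs.

    Adjusted p-values come from the studentized-range distribution with
    the Tukey-Kramer standard error for unequal group sizes. The returned
    result also carries the omnibus ANOVA F and p.
    """
    f_stat, p = one_way_anova(groups)
    values = [np.asarray(g.replicate_values, dtype=float) for g in groups]
    labels = [g.group_label for g in groups]
    res = sps.tukey_hsd(*values)
    pairwise = []
    for i, j in itertools.combinations(range(len(groups)), 2):
        diff = float(values[i].mean() - values[j].mean())
        pairwise.append((labels[i], labels[j], diff, float(res.pvalue[i, j])))
    return AnovaTukeyResult(F_statistic=f_stat, p_value=p, pairwise=tuple(pairwise))


def significance_stars(p: float) -> str:
    """Figure-caption star convention: * <0.05, ** <0.01, *** <0.001,
    **** <0.0001; 'ns' otherwise."""
    if not 0.0 <= p <= 1.0:
        raise ValueError("p must be in [0, 1]")
    for stars, cut in (("****", 1e-4), ("***", 1e-3), ("**", 1e-2), ("*", 0.05)):
        if p < cut:
            return stars
    return "ns"


# ---------------------------------------------------------------------------
# Dose-response summary


def dose_response_summary(
    table: ExperimentTable, fold_mode: str = "mean-ratio"
) -> UptakeSummary:
    """Per-group mean/SD, fold versus sham, and the optimal PNP.

    The optimal PNP is the insonated (TMB+US) group with the largest mean;
    ties break toward the lower pressure.
    """
    insonated = [g for g in table.groups if g.pnp_kpa is not None]
    if not insonated:
        raise ValueError("table has no insonated (tmb_us_*) group")
    sham = table.sham
    means = {g.group_label: g.mean for g in table.groups}
    sds = {g.group_label: g.sd for g in table.groups}
    folds = {}
    for g in table.groups:
        f = fold_uptake(g, sham, mode=fold_mode)
        folds[g.group_label] = f[0] if isinstance(f, tuple) else f
    best = max(
        sorted(insonated, key=lambda g: g.pnp_kpa),
        key=lambda g: g.mean,
    )
    # max() keeps the first of equal-mean candidates, i.e. the lower PNP
    return UptakeSummary(
        molecule=table.molecule,
        metric=table.metric,
        timepoint_h=table.timepoint_h,
        group_means=means,
        group_sds=sds,
        fold_vs_sham=folds,
        optimal_pnp_kpa=float(best.pnp_kpa),
    )


def analyze_table(
    table: ExperimentTable,
    fold_mode: str = "mean-ratio",
    alpha: float = 0.05,
) -> dict:
    """Full report for one experiment: summaries, folds, ANOVA and Tukey
    pairs with significance stars. JSON-serializable."""
    summary = dose_response_summary(table, fold_mode=fold_mode)
    anova = tukey_hsd(list(table.groups), alpha=alpha)
    return {
        "molecule": table.molecule,
        "metric": table.metric,
        "timepoint_h": table.timepoint_h,
        "groups": {
            g.group_label: {
                "n": g.n_replicates,
                "mean": g.mean,
                "sd": g.sd,
                "fold_vs_sham": summary.fold_vs_sham[g.group_label],
            }
            for g in table.groups
        },
        "optimal_pnp_kpa": summary.optimal_pnp_kpa,
        "anova": {"F": anova.F_statistic, "p": anova.p_value},
        "tukey": [
            {
                "group_a": a,
                "group_b": b,
                "mean_diff": diff,
                "adjusted_p": p,
                "stars": significance_stars(p),
            }
            for a, b, diff, p in anova.pairwise
        ],
    }


def write_report(report: dict, path: str | Path) -> None:
    Path(path).write_text(json.dumps(report, indent=2))
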