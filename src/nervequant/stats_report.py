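"""Cohort aggregation and group statistics.

Per-frame measurements are averaged per subject before any group test (each
subject contributes several stills per site, typically six). Group
comparisons follow the common clinical-statistics recipe: assess normality
per group (D'Agostino–Pearson for n >= 8, Shapiro–Wilk for 3 <= n < 8,
nonparametric forced below that); if every group passes, use one-way ANOVA
with Tukey's HSD post hoc, otherwise Mann–Whitney U for two groups or
Kruskal–Wallis with Dunn's post hoc (Bonferroni-adjusted) for more.
Significance stars use the inclusive boundaries p <= 0.05 (*), p <= 0.01
(**), p <= 0.001 (***). Correlations are Pearson's r with a two-sided p.

This is a thin layer over scipy; only Dunn's post hoc (rank-based pairwise z
tests with tie correction) is implemented here, as no installed package
provides it.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from itertools import combinations
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .errors import UndefinedCorrelationError, ValidationError

__all__ = [
    "SITES",
    "SubjectRecord",
    "aggregate_per_subject",
    "table_from_group_values",
    "significance_stars",
    "GroupComparison",
    "PairwiseResult",
    "compare_groups",
    "correlate",
]

SITES = (
    "neuroma",
    "unaffected",
    "healthy_control",
    "muscle_denervated",
    "muscle_control",
)

NORMALITY_ALPHA = 0.05


@dataclass(frozen=True)
class SubjectRecord:
    """Per-frame measurements of one metric for one subject at one site."""

    subject_id: str
    site: str
    metric: str
    measurements: tuple[float, ...]

    def __post_init__(self) -> None:
        if self.site not in SITES:
            raise ValidationError(f"site must be one of {SITES}, got {self.site!r}")
        vals = tuple(float(v) for v in self.measurements)
        if len(vals) < 1:
            raise ValidationError("a subject record needs at least one measurement")
        object.__setattr__(self, "measurements", vals)


def aggregate_per_subject(records: Sequence[SubjectRecord]) -> pd.DataFrame:
    """Cohort table: one row per subject × site × metric with the arithmetic
    mean of that subject's per-frame values."""
    rows = [
        {
            "subject_id": r.subject_id,
            "site": r.site,
            "metric": r.metric,
            "mean": float(np.mean(r.measurements)),
        }
        for r in records
    ]
    table = pd.DataFrame(rows, columns=["subject_id", "site", "metric", "mean"])
    if len(table) and table.duplicated(["subject_id", "site", "metric"]).any():
        raise ValidationError("duplicate subject × site × metric rows")
    return table


def table_from_group_values(
    metric: str, groups: dict[str, Sequence[float]]
) -> pd.DataFrame:
    """Build a cohort table directly from per-subject values (one value per
    subject) — convenient for Monte-Carlo work on the test layer."""
    records = [
        SubjectRecord(f"{site}_s{i:02d}", site, metric, (float(v),))
        for site, values in groups.items()
        for i, v in enumerate(values)
    ]
    return aggregate_per_subject(records)


def significance_stars(p: float) -> str:
    """Star coding with inclusive boundaries: <=0.05 *, <=0.01 **, <=0.001 ***."""
    if p <= 0.001:
        return "***"
    if p <= 0.01:
        return "**"
    if p <= 0.05:
        return "*"
    return ""


@dataclass(frozen=True)
class PairwiseResult:
    group_a: str
    group_b: str
    pvalue: float
    stars: str


@dataclass(frozen=True)
class GroupComparison:
    """Result of an omnibus group test plus post hoc pairwise comparisons."""

    metric: str
    groups: tuple[str, ...]
    test_name: str
    statistic: float
    pvalue: float
    stars: str
    normality: dict = field(default_factory=dict)
    posthoc: tuple[PairwiseResult, ...] = ()
    notes: tuple[str, ...] = ()


def _normality(values: np.ndarray) -> tuple[str, float | None, bool]:
    """(test name, p, passed). Zero-variance groups cannot be called normal."""
    n = values.size
    if np.ptp(values) == 0:
        return ("constant", None, False)
    if n >= 8:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            p = float(sps.normaltest(values).pvalue)
        return ("dagostino_pearson", p, p > NORMALITY_ALPHA)
    if n >= 3:
        p = float(sps.shapiro(values).pvalue)
        return ("shapiro_wilk", p, p > NORMALITY_ALPHA)
    return ("too_small", None, False)


def _dunn_posthoc(
    names: Sequence[str], samples: Sequence[np.ndarray]
) -> list[PairwiseResult]:
    """Dunn's multiple-comparison test: pairwise z statistics on pooled mean
    ranks with tie correction, Bonferroni-adjusted over all pairs."""
    pooled = np.concatenate(samples)
    n_total = pooled.size
    ranks = sps.rankdata(pooled)
    mean_ranks, sizes = [], []
    start = 0
    for s in samples:
        mean_ranks.append(ranks[start : start + s.size].mean())
        sizes.append(s.size)
        start += s.size
    _, tie_counts = np.unique(pooled, return_counts=True)
    tie_term = float(np.sum(tie_counts**3 - tie_counts))
    m = len(names) * (len(names) - 1) // 2
    out = []
    for i, j in combinations(range(len(names)), 2):
        var = (
            n_total * (n_total + 1) / 12.0 - tie_term / (12.0 * (n_total - 1))
        ) * (1.0 / sizes[i] + 1.0 / sizes[j])
        if var <= 0:
            p = 1.0
        else:
            z = abs(mean_ranks[i] - mean_ranks[j]) / np.sqrt(var)
            p = min(1.0, 2.0 * sps.norm.sf(z) * m)
        out.append(PairwiseResult(names[i], names[j], float(p), significance_stars(p)))
    return out


def compare_groups(
    table: pd.DataFrame, metric: str, groups: Sequence[str]
) -> GroupComparison:
    """Omnibus comparison of per-subject means across sites.

    The parametric/nonparametric route is decided by the per-group normality
    gate described in the module docstring; the chosen route, the normality
    results, and the post hoc adjustment are all reported so the decision is
    auditable.
    """
    groups = tuple(groups)
    if len(groups) < 2:
        raise ValidationError("need at least two groups to compare")
    sub = table[table["metric"] == metric]
    samples = []
    for g in groups:
        vals = sub.loc[sub["site"] == g, "mean"].to_numpy(dtype=float)
        if vals.size < 2:
            raise ValidationError(f"group {g!r} has n < 2 subjects for {metric!r}")
        samples.append(vals)

    normality = {g: _normality(v) for g, v in zip(groups, samples)}
    all_normal = all(passed for (_, _, passed) in normality.values())
    notes = [
        "normality gate: D'Agostino-Pearson for n>=8, Shapiro-Wilk for 3<=n<8, "
        "nonparametric forced below n=3",
    ]

    if np.ptp(np.concatenate(samples)) == 0:
        # All values identical across all groups: no evidence of any effect.
        return GroupComparison(
            metric, groups, "degenerate (all values equal)", 0.0, 1.0, "",
            normality=normality, notes=tuple(notes),
        )

    posthoc: list[PairwiseResult] = []
    if all_normal:
        res = sps.f_oneway(*samples)
        test_name, stat, p = "one-way ANOVA", float(res.statistic), float(res.pvalue)
        tk = sps.tukey_hsd(*samples)
        for i, j in combinations(range(len(groups)), 2):
            pv = float(tk.pvalue[i, j])
            posthoc.append(PairwiseResult(groups[i], groups[j], pv, significance_stars(pv)))
        notes.append("post hoc: Tukey HSD")
    elif len(groups) == 2:
        res = sps.mannwhitneyu(samples[0], samples[1], alternative="two-sided")
        test_name, stat, p = "Mann-Whitney U", float(res.statistic), float(res.pvalue)
    else:
        res = sps.kruskal(*samples)
        test_name, stat, p = "Kruskal-Wallis", float(res.statistic), float(res.pvalue)
        posthoc = _dunn_posthoc(groups, samples)
        notes.append("post hoc: Dunn, Bonferroni-adjusted")

    return GroupComparison(
        metric=metric,
        groups=groups,
        test_name=test_name,
        statistic=stat,
        pvalue=p,
        stars=significance_stars(p),
        normality=normality,
        posthoc=tuple(posthoc),
        notes=tuple(notes),
    )


def correlate(table: pd.DataFrame, metric_x: str, metric_y: str) -> tuple[float, float]:
    """Pearson correlation of two metrics paired per subject × site.

    Returns (r, two-sided p). Raises on fewer than 3 pairs or zero variance.
    """
    wide = (
        table[table["metric"].isin([metric_x, metric_y])]
        .pivot_table(index=["subject_id", "site"], columns="metric", values="mean")
        .dropna()
    )
    if metric_x not in wide.columns or metric_y not in wide.columns or len(wide) < 3:
        raise ValidationError("correlation needs >= 3 paired subject values")
    x = wide[metric_x].to_numpy(dtype=float)
    y = wide[metric_y].to_numpy(dtype=float)
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise UndefinedCorrelationError("correlation undefined for a constant metric")
    r, p = sps.pearsonr(x, y)
    return float(r), float(p)
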