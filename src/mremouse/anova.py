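"""Longitudinal statistics: mixed-design and between-subjects two-way
ANOVAs, and Bonferroni-adjusted pairwise comparisons.

The repeated-measures (mixed-design, "split-plot") two-way ANOVA treats
Treatment as the between-subjects factor and Time (and Treatment x Time)
as within-subjects factors, with two error strata:

* between-subjects stratum: Treatment tested against subjects-within-groups;
* within-subjects stratum: Time and the interaction tested against
  Time x subjects-within-groups.

No sphericity correction is applied by default, so for 2 groups x n
subjects x t time points the degrees of freedom are Treatment (1, 2n-2),
Time (t-1, (2n-2)(t-1)) and interaction (t-1, (2n-2)(t-1)). All sums of
squares are computed by direct summation over cell/marginal means, which
keeps each stratum's decomposition explicit and exactly additive.

The fully-between two-way ANOVA covers the histology-style design where
separate animal groups are sacrificed per time point.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "EffectRow",
    "AnovaResult",
    "PairwiseComparison",
    "ComparisonFamily",
    "rm_two_way_anova",
    "two_way_anova",
    "bonferroni_pairwise",
]


@dataclass(frozen=True)
class EffectRow:
    """One tested effect: its SS/df and the error term it was tested against."""

    effect: str
    ss: float
    df: int
    error_ss: float
    error_df: int
    stratum: str
    f: float
    p: float

    @property
    def ms(self) -> float:
        return self.ss / self.df

    @property
    def error_ms(self) -> float:
        return self.error_ss / self.error_df


@dataclass
class AnovaResult:
    """Collection of tested effects plus the total SS for additivity checks."""

    design: str
    effects: dict[str, EffectRow]
    ss_total: float
    degenerate: bool = False  # zero total SS; F undefined

    def __getitem__(self, effect: str) -> EffectRow:
        return self.effects[effect]

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {
                "effect": e.effect,
                "ss": e.ss,
                "df": e.df,
                "ms": e.ms,
                "F": e.f,
                "p": e.p,
                "error_ss": e.error_ss,
                "error_df": e.error_df,
                "stratum": e.stratum,
            }
            for e in self.effects.values()
        ]
        return pd.DataFrame(rows)


def _f_test(ss: float, df: int, error_ss: float, error_df: int) -> tuple[float, float]:
    if error_ss <= 0 or df <= 0 or error_df <= 0:
        return float("nan"), float("nan")
    f = (ss / df) / (error_ss / error_df)
    return f, float(stats.f.sf(f, df, error_df))


def _study_matrix(
    table: pd.DataFrame, parameter: str | None, roi: str | None
) -> tuple[np.ndarray, np.ndarray, list[str]]:
    """Pivot a long study table to a subjects x time matrix plus group labels."""
    sub = table
    if parameter is not None:
        sub = sub[sub["parameter"] == parameter]
    if roi is not None:
        sub = sub[sub["roi"] == roi]
    if sub.empty:
        raise ValueError(f"no records for parameter={parameter!r}, roi={roi!r}")

    counts = sub.groupby(["treatment", "time_point"], observed=True)["value"].count()
    if counts.nunique() != 1:
        offender = counts.idxmin()
        raise ValueError(
            f"unbalanced design: cell {offender} has {counts.min()} records "
            f"while others have up to {counts.max()}"
        )
    dup = sub.groupby(["animal_id", "time_point"], observed=True)["value"].count()
    if (dup != 1).any():
        offender = dup[dup != 1].index[0]
        raise ValueError(f"expected one record per (animal, time), got {dup.max()} at {offender}")

    time_order = list(pd.unique(sub["time_point"]))
    wide = sub.pivot(index="animal_id", columns="time_point", values="value")[time_order]
    if wide.isna().any().any():
        missing = wide.stack(dropna=False)
        cell = missing[missing.isna()].index[0]
        raise ValueError(f"missing cell in design: {cell}")
    groups = sub.drop_duplicates("animal_id").set_index("animal_id")["treatment"]
    groups = groups.loc[wide.index].to_numpy()
    return wide.to_numpy(float), groups, time_order


def rm_two_way_anova(
    table: pd.DataFrame, parameter: str | None = None, roi: str | None = None
) -> AnovaResult:
    """Mixed-design two-way ANOVA on a long-format study table.

    Requires a balanced, complete design: equal subjects per treatment and
    one record per (animal, time point) after filtering to ``parameter``
    and ``roi``.
    """
    y, groups, times = _study_matrix(table, parameter, roi)
    n_subj, n_time = y.shape
    levels = list(pd.unique(groups))
    if len(levels) < 2:
        raise ValueError(f"need at least 2 treatment groups, got {levels}")
    sizes = [int((groups == g).sum()) for g in levels]
    if len(set(sizes)) != 1:
        raise ValueError(f"unequal group sizes {dict(zip(levels, sizes))}")
    n = sizes[0]
    n_grp = len(levels)

    grand = y.mean()
    ss_total = float(((y - grand) ** 2).sum())

    subj_means = y.mean(axis=1)
    group_means = np.array([y[groups == g].mean() for g in levels])
    time_means = y.mean(axis=0)
    cell_means = np.array([y[groups == g].mean(axis=0) for g in levels])  # (g, t)

    ss_between_subj = n_time * float(((subj_means - grand) ** 2).sum())
    ss_treatment = n_time * n * float(((group_means - grand) ** 2).sum())
    ss_subj_within = ss_between_subj - ss_treatment

    ss_within_subj = ss_total - ss_between_subj
    ss_time = n_subj * float(((time_means - grand) ** 2).sum())
    ss_inter = n * float(
        (
            (cell_means - group_means[:, None] - time_means[None, :] + grand) ** 2
        ).sum()
    )
    ss_err_within = ss_within_subj - ss_time - ss_inter

    df_treat, df_subj = n_grp - 1, n_grp * (n - 1)
    df_time = n_time - 1
    df_inter = (n_grp - 1) * (n_time - 1)
    df_err_w = n_grp * (n - 1) * (n_time - 1)

    degenerate = ss_total <= 0
    effects = {}
    for name, ss, df, ess, edf, stratum in (
        ("treatment", ss_treatment, df_treat, ss_subj_within, df_subj, "between_subjects"),
        ("time", ss_time, df_time, ss_err_within, df_err_w, "within_subjects"),
        ("treatment:time", ss_inter, df_inter, ss_err_within, df_err_w, "within_subjects"),
    ):
        f, p = (float("nan"), float("nan")) if degenerate else _f_test(ss, df, ess, edf)
        effects[name] = EffectRow(name, ss, df, ess, edf, stratum, f, p)

    return AnovaResult(
        design="rm_two_way", effects=effects, ss_total=ss_total, degenerate=degenerate
    )


def two_way_anova(
    table: pd.DataFrame,
    value: str = "value",
    factor_a: str = "treatment",
    factor_b: str = "time_point",
) -> AnovaResult:
    """Fully-between two-way fixed-effects ANOVA on a long-format table.

    One observation per (animal, cell); balanced cells required. All three
    effects are tested against the single residual error term. With all
    observations equal (zero total SS) the F statistics are flagged
    undefined rather than raised.
    """
    for col in (value, factor_a, factor_b):
        if col not in table.columns:
            raise ValueError(f"table lacks required column {col!r}")
    counts = table.groupby([factor_a, factor_b], observed=True)[value].count()
    if counts.nunique() != 1:
        offender = counts.idxmin()
        raise ValueError(
            f"unbalanced design: cell {offender} has {counts.min()} observations "
            f"while others have up to {counts.max()}"
        )
    n = int(counts.iloc[0])
    if n < 2:
        raise ValueError("need at least 2 observations per cell")

    a_levels = list(pd.unique(table[factor_a]))
    b_levels = list(pd.unique(table[factor_b]))
    n_a, n_b = len(a_levels), len(b_levels)
    y = np.empty((n_a, n_b, n), dtype=float)
    for i, a in enumerate(a_levels):
        for j, b in enumerate(b_levels):
            y[i, j] = table[(table[factor_a] == a) & (table[factor_b] == b)][value].to_numpy()

    grand = y.mean()
    ss_total = float(((y - grand) ** 2).sum())
    a_means = y.mean(axis=(1, 2))
    b_means = y.mean(axis=(0, 2))
    cell_means = y.mean(axis=2)

    ss_a = n_b * n * float(((a_means - grand) ** 2).sum())
    ss_b = n_a * n * float(((b_means - grand) ** 2).sum())
    ss_ab = n * float(
        ((cell_means - a_means[:, None] - b_means[None, :] + grand) ** 2).sum()
    )
    ss_err = ss_total - ss_a - ss_b - ss_ab

    df_a, df_b = n_a - 1, n_b - 1
    df_ab = df_a * df_b
    df_err = n_a * n_b * (n - 1)

    degenerate = ss_total <= 0
    effects = {}
    for name, ss, df in ((factor_a, ss_a, df_a), (factor_b, ss_b, df_b), (f"{factor_a}:{factor_b}", ss_ab, df_ab)):
        f, p = (float("nan"), float("nan")) if degenerate else _f_test(ss, df, ss_err, df_err)
        effects[name] = EffectRow(name, ss, df, ss_err, df_err, "residual", f, p)

    return AnovaResult(
        design="two_way_between", effects=effects, ss_total=ss_total, degenerate=degenerate
    )


@dataclass(frozen=True)
class PairwiseComparison:
    """One Bonferroni-adjusted contrast within an explicitly sized family."""

    family_id: str
    contrast: str
    t: float
    df: int
    raw_p: float
    adjusted_p: float
    family_size: int


@dataclass
class ComparisonFamily:
    """Explicit enumeration of one family of pairwise comparisons.

    ``kind='treatment_within_time'`` compares the two treatment groups at
    each listed time point (independent-samples t); default family size is
    the 6 time points. ``kind='time_within_treatment'`` compares listed
    time-point pairs within one treatment group (paired t across animals);
    default family is all 15 pairs of the 6 time points.
    """

    family_id: str
    kind: str
    parameter: str | None = None
    roi: str | None = None
    treatment: str | None = None
    times: tuple[str, ...] | None = None
    pairs: tuple[tuple[str, str], ...] | None = None

    def __post_init__(self) -> None:
        if self.kind not in ("treatment_within_time", "time_within_treatment"):
            raise ValueError(f"unknown family kind {self.kind!r}")
        if self.kind == "time_within_treatment" and self.treatment is None:
            raise ValueError("time_within_treatment family needs a treatment group")


def _filter(table: pd.DataFrame, family: ComparisonFamily) -> pd.DataFrame:
    sub = table
    if family.parameter is not None and "parameter" in sub.columns:
        sub = sub[sub["parameter"] == family.parameter]
    if family.roi is not None and "roi" in sub.columns:
        sub = sub[sub["roi"] == family.roi]
    if sub.empty:
        raise ValueError(f"no records match family {family.family_id!r}")
    return sub


def bonferroni_pairwise(
    table: pd.DataFrame, family: ComparisonFamily
) -> list[PairwiseComparison]:
    """Bonferroni-adjusted two-sample t comparisons for one explicit family.

    The adjusted p is min(1, m * raw_p) with m the number of comparisons in
    the family. Group-at-time contrasts use a pooled-variance
    independent-samples t over animals at that time point; time-pair
    contrasts within a group use a paired t across animals. The per-contrast
    error term (rather than a pooled model stratum term) is a documented
    implementation choice.
    """
    sub = _filter(table, family)
    comparisons: list[PairwiseComparison] = []

    if family.kind == "treatment_within_time":
        times = (
            family.times
            if family.times is not None
            else tuple(pd.unique(sub["time_point"]))
        )
        if len(times) == 0:
            raise ValueError("empty comparison family")
        m = len(times)
        treatments = list(pd.unique(sub["treatment"]))
        if len(treatments) != 2:
            raise ValueError(f"need exactly 2 treatment groups, got {treatments}")
        for tp in times:
            a = sub[(sub["time_point"] == tp) & (sub["treatment"] == treatments[0])]["value"]
            b = sub[(sub["time_point"] == tp) & (sub["treatment"] == treatments[1])]["value"]
            res = stats.ttest_ind(a, b, equal_var=True)
            df = len(a) + len(b) - 2
            comparisons.append(
                PairwiseComparison(
                    family_id=family.family_id,
                    contrast=f"{treatments[0]} vs {treatments[1]} @ {tp}",
                    t=float(res.statistic),
                    df=df,
                    raw_p=float(res.pvalue),
                    adjusted_p=min(1.0, m * float(res.pvalue)),
                    family_size=m,
                )
            )
    else:
        sub = sub[sub["treatment"] == family.treatment]
        if sub.empty:
            raise ValueError(f"no records for treatment {family.treatment!r}")
        if family.pairs is not None:
            pairs = family.pairs
        else:
            times = (
                family.times
                if family.times is not None
                else tuple(pd.unique(sub["time_point"]))
            )
            pairs = tuple(combinations(times, 2))
        if len(pairs) == 0:
            raise ValueError("empty comparison family")
        m = len(pairs)
        wide = sub.pivot(index="animal_id", columns="time_point", values="value")
        for t1, t2 in pairs:
            res = stats.ttest_rel(wide[t1], wide[t2])
            comparisons.append(
                PairwiseComparison(
                    family_id=family.family_id,
                    contrast=f"{t1} vs {t2} @ {family.treatment}",
                    t=float(res.statistic),
                    df=len(wide) - 1,
                    raw_p=float(res.pvalue),
                    adjusted_p=min(1.0, m * float(res.pvalue)),
                    family_size=m,
                )
            )
    return comparisons
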