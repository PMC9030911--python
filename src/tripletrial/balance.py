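"""Baseline balance diagnostics across the three study arms.

Categorical covariates are tested with Pearson chi-square tests (no
continuity correction, which is what reproduces the published
statistics); the two continuous covariates (age, household size) with
one-way ANOVA. Each variable uses its own complete cases, so the
per-row n varies with item missingness, as in the published balance
table.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy import stats

from .records import ARMS, CountTable, ParticipantRecord, to_frame

#: Balance variables in report order: (field, test kind).
BALANCE_VARIABLES = (
    ("district", "chisq"),
    ("age", "anova"),
    ("education", "chisq"),
    ("married", "chisq"),
    ("has_children", "chisq"),
    ("phone_self_owned", "chisq"),
    ("household_size", "anova"),
    ("driving_setting", "chisq"),
    ("night_freq", "chisq"),
    ("baseline_consistent", "chisq"),
    ("speeding_freq", "chisq"),
    ("weekend_freq", "chisq"),
)


@dataclass
class BalanceRow:
    """One balance-table line: test statistic and per-arm summaries."""

    variable: str
    test: str  # 'chisq' | 'anova'
    statistic: float
    df: object  # int for chi-square, (df1, df2) for ANOVA
    p_value: float
    n: int
    summaries: dict = field(default_factory=dict)
    flag: Optional[str] = None


def chisq_test(table: CountTable, variable: str = "") -> BalanceRow:
    """Pearson chi-square on a levels-by-arms count table."""
    counts = table.counts
    if (counts.sum(axis=1) == 0).any():
        bad = [table.row_labels[i] for i in
               np.flatnonzero(counts.sum(axis=1) == 0)]
        raise ValueError(f"zero row margin for level(s) {bad}")
    if (counts.sum(axis=0) == 0).any():
        bad = [table.col_labels[j] for j in
               np.flatnonzero(counts.sum(axis=0) == 0)]
        raise ValueError(f"zero column margin for arm(s) {bad}")
    statistic, p, df, _ = stats.chi2_contingency(counts, correction=False)
    summaries = {col: dict(zip(table.row_labels, counts[:, j].tolist()))
                 for j, col in enumerate(table.col_labels)}
    return BalanceRow(variable=variable, test="chisq",
                      statistic=float(statistic), df=int(df),
                      p_value=float(p), n=table.n, summaries=summaries)


def anova_oneway(groups: Sequence[Sequence[float]],
                 labels: Optional[Sequence[str]] = None,
                 variable: str = "") -> BalanceRow:
    """One-way ANOVA F test across arm groups."""
    groups = [np.asarray(g, dtype=float) for g in groups]
    if len(groups) < 2 or any(len(g) < 2 for g in groups):
        raise ValueError("ANOVA needs >=2 groups with >=2 observations each")
    labels = list(labels) if labels else [f"g{i}" for i in range(len(groups))]
    n = sum(len(g) for g in groups)
    df = (len(groups) - 1, n - len(groups))
    pooled = np.concatenate(groups)
    flag = None
    if all(np.ptp(g) == 0 for g in groups):
        if np.ptp(pooled) == 0:
            statistic, p = 0.0, 1.0
        else:
            statistic, p, flag = math.inf, 0.0, "zero_within_variance"
    else:
        statistic, p = stats.f_oneway(*groups)
    summaries = {lab: {"mean": float(np.mean(g)),
                       "sd": float(np.std(g, ddof=1)), "n": len(g)}
                 for lab, g in zip(labels, groups)}
    return BalanceRow(variable=variable, test="anova",
                      statistic=float(statistic), df=df, p_value=float(p),
                      n=n, summaries=summaries, flag=flag)


def balance_table(records: Sequence[ParticipantRecord]) -> list[BalanceRow]:
    """Balance diagnostics for every baseline variable, by assigned arm.

    Complete cases per variable; variables with a single observed level
    (or with an arm entirely missing) are skipped with a flagged row.
    """
    frame = to_frame(records)
    arms_present = sorted(set(frame["arm"].dropna()))
    if len(arms_present) < 2:
        raise ValueError("balance requires at least two assigned arms")
    rows = []
    for variable, test in BALANCE_VARIABLES:
        sub = frame[frame["arm"].notna() & frame[variable].notna()]
        if test == "anova":
            groups = [sub.loc[sub["arm"] == a, variable]
                      .to_numpy(dtype=float) for a in arms_present]
            if any(len(g) < 2 for g in groups):
                rows.append(BalanceRow(variable, test, math.nan, None,
                                       math.nan, len(sub),
                                       flag="insufficient_data"))
                continue
            rows.append(anova_oneway(groups, labels=arms_present,
                                     variable=variable))
        else:
            levels = sorted(sub[variable].unique(), key=str)
            counts = np.array(
                [[int(((sub["arm"] == a) & (sub[variable] == lv)).sum())
                  for a in arms_present] for lv in levels])
            keep = counts.sum(axis=1) > 0
            counts, levels = counts[keep], [lv for lv, k in
                                            zip(levels, keep) if k]
            if counts.shape[0] < 2:
                rows.append(BalanceRow(variable, test, math.nan, None,
                                       math.nan, len(sub),
                                       flag="single_level"))
                continue
            table = CountTable(tuple(str(lv) for lv in levels),
                               tuple(arms_present), counts)
            rows.append(chisq_test(table, variable=variable))
    return rows
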