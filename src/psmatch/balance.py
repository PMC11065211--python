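"""Covariate balance diagnostics for matched case-control cohorts.

One row per clinicopathological covariate, before and after matching:
continuous and ordinal covariates are summarized by group means and
compared with a Student (pooled-variance) t-test; categorical covariates by
per-level counts and a chi-squared test — Yates continuity-corrected for
2x2 tables (the convention the reference contingency p-values require),
plain Pearson for 2xK with K > 2. Significance is flagged at p < 0.05 per
covariate with no multiplicity correction, matching how such cohort tables
are conventionally reported.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, NamedTuple, Sequence

import numpy as np
import pandas as pd
import scipy.stats

from .cohort import Cohort

__all__ = [
    "TTestResult",
    "ChisqResult",
    "BalanceTable",
    "student_t_test",
    "chisq_yates",
    "balance_table",
]

ALPHA = 0.05


class TTestResult(NamedTuple):
    statistic: float
    pvalue: float


class ChisqResult(NamedTuple):
    statistic: float
    pvalue: float
    dof: int
    low_expected: bool  # any expected cell count < 5


def student_t_test(x: Sequence[float], y: Sequence[float]) -> TTestResult:
    """Two-sided pooled-variance (equal-variance) Student t-test."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) < 2 or len(y) < 2:
        raise ValueError("each sample needs at least 2 values")
    if np.var(x, ddof=1) + np.var(y, ddof=1) <= 0:
        raise ValueError("zero pooled variance: t statistic undefined")
    stat, p = scipy.stats.ttest_ind(x, y, equal_var=True)
    return TTestResult(float(stat), float(p))


def welch_t_test(x: Sequence[float], y: Sequence[float]) -> TTestResult:
    """Welch (unequal-variance) alternative, exposed as a config switch."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) < 2 or len(y) < 2:
        raise ValueError("each sample needs at least 2 values")
    if np.var(x, ddof=1) + np.var(y, ddof=1) <= 0:
        raise ValueError("zero pooled variance: t statistic undefined")
    stat, p = scipy.stats.ttest_ind(x, y, equal_var=False)
    return TTestResult(float(stat), float(p))


def chisq_yates(table) -> ChisqResult:
    """Chi-squared test on a 2xK contingency table.

    2x2 tables get the Yates continuity correction (statistic
    sum((|O - E| - 0.5)^2 / E), 1 df); wider tables the uncorrected Pearson
    statistic with K - 1 df. Expected counts below 5 are flagged in the
    result, not fatal.
    """
    t = np.asarray(table, dtype=float)
    if t.ndim != 2 or t.shape[0] != 2 or t.shape[1] < 2:
        raise ValueError("expected a 2xK contingency table with K >= 2")
    if np.any(t < 0) or not np.allclose(t, np.round(t)):
        raise ValueError("counts must be non-negative integers")
    if np.any(t.sum(axis=0) == 0) or np.any(t.sum(axis=1) == 0):
        raise ValueError("zero row or column margin")
    correction = t.shape == (2, 2)
    stat, p, dof, expected = scipy.stats.chi2_contingency(t, correction=correction)
    return ChisqResult(float(stat), float(p), int(dof), bool((expected < 5).any()))


@dataclass
class BalanceTable:
    """Tables-1/3-style side-by-side pre/post balance diagnostic."""

    table: pd.DataFrame
    pre_group_sizes: tuple[int, int]  # (good, poor)
    post_group_sizes: tuple[int, int]

    def to_markdown(self) -> str:
        ng, np_ = self.pre_group_sizes
        mg, mp = self.post_group_sizes
        head = (
            f"Covariate balance before matching (good N={ng}, poor N={np_}) "
            f"and after matching (good N={mg}, poor N={mp}). "
            f"* marks p < {ALPHA}.\n\n"
        )
        df = self.table.copy()
        for col in ("pre_p", "post_p"):
            flag = df[col].lt(ALPHA).fillna(False)
            df[col] = df[col].map(lambda v: "" if pd.isna(v) else f"{v:.4g}")
            df.loc[flag, col] = df.loc[flag, col] + "*"
        return head + df.to_markdown(index=False)


def _summarize(cohort: Cohort, name: str, kind: str):
    """(summary-good, summary-poor, test name, p-value) for one covariate."""
    x = cohort.covariates[name]
    good = x[cohort.outcome == 0]
    poor = x[cohort.outcome == 1]
    if kind in ("continuous", "ordinal"):
        s_g, s_p = f"{good.mean():.4g}", f"{poor.mean():.4g}"
        try:
            p = student_t_test(good, poor).pvalue
        except ValueError:
            p = np.nan  # covariate constant: test undefined, row flagged
        return s_g, s_p, "t", p
    levels = sorted(pd.unique(x))
    counts = np.array(
        [[(good == lv).sum() for lv in levels], [(poor == lv).sum() for lv in levels]]
    )
    s_g = ";".join(f"{lv}:{c}" for lv, c in zip(levels, counts[0]))
    s_p = ";".join(f"{lv}:{c}" for lv, c in zip(levels, counts[1]))
    if len(levels) < 2:
        return s_g, s_p, "chisq", np.nan
    p = chisq_yates(counts).pvalue
    return s_g, s_p, "chisq", p


def balance_table(
    pre_cohort: Cohort,
    post_cohort: Cohort,
    kinds: Mapping[str, str] | None = None,
    categorical_test_for_binary: bool = True,
) -> BalanceTable:
    """Compare covariate balance before vs after matching.

    ``kinds`` defaults to the pre-cohort's declared covariate kinds; binary
    covariates are tested as 2x2 contingency tables, continuous and ordinal
    ones as mean differences.
    """
    kinds = dict(kinds or pre_cohort.kinds)
    if set(kinds) - set(post_cohort.covariates.columns):
        raise ValueError("pre and post cohorts must share the covariate schema")
    rows = []
    for name, kind in kinds.items():
        test_kind = kind
        if kind == "binary" and not categorical_test_for_binary:
            test_kind = "continuous"
        g0, p0, test, pre_p = _summarize(pre_cohort, name, test_kind)
        g1, p1, _, post_p = _summarize(post_cohort, name, test_kind)
        rows.append(
            {
                "covariate": name,
                "kind": kind,
                "test": test,
                "pre_good": g0,
                "pre_poor": p0,
                "pre_p": pre_p,
                "pre_significant": bool(pre_p < ALPHA) if pre_p == pre_p else False,
                "post_good": g1,
                "post_poor": p1,
                "post_p": post_p,
                "post_significant": bool(post_p < ALPHA) if post_p == post_p else False,
            }
        )
    return BalanceTable(
        table=pd.DataFrame(rows),
        pre_group_sizes=pre_cohort.group_sizes,
        post_group_sizes=post_cohort.group_sizes,
    )
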