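"""Pre/post-matching differential marker analysis.

Two marker layers are supported:

* **Score panels** (immunohistochemistry-style): per-marker group means
  compared with a Student t-test for bounded scores, or positive-call
  counts compared with a Yates-corrected chi-squared for binary markers.
  Raw p-values at 0.05, no multiplicity correction — the convention for
  small curated panels.

* **Count matrices** (RNA-seq-like): library-size normalization to counts
  per million (CPM), removal of low-expression genes (CPM below a
  threshold, default 15), a log2(CPM + 0.5) transform, a per-gene Welch
  t-test of poor vs good prognosis, and Benjamini-Hochberg FDR control at
  0.05. This is a deliberately simple, transparent substitute for the
  moderated pipelines (TMM + voom + empirical-Bayes shrinkage) usually
  applied to such data; it shares their structure (normalize, filter,
  test, adjust) but not their gene-wise variance pooling, and result
  metadata records that choice.

Significant sets from two analyses (e.g. before vs after matching) are
compared as a disjoint shared / pre-only / post-only partition with a
volcano-style export.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import scipy.stats
from statsmodels.stats.multitest import multipletests

from .balance import chisq_yates, student_t_test
from .cohort import CohortError

__all__ = [
    "DifferentialConfig",
    "DifferentialResult",
    "SetComparison",
    "compare_score_panel",
    "cpm",
    "filter_low_expression",
    "differential_expression",
    "bh_adjust",
    "compare_sets",
]


@dataclass(frozen=True)
class DifferentialConfig:
    """Thresholds and rule choices for the count-layer analysis.

    cpm_threshold
        CPM below which a gene counts as unexpressed in a subject.
    fdr_threshold
        BH-adjusted significance cutoff.
    filter_rule
        ``min_group``: keep genes with CPM >= threshold in at least
        min(group sizes) subjects (filterByExpr-like); ``mean``: keep genes
        whose mean CPM >= threshold.
    test
        ``welch`` (default) or ``student`` per-gene test on log2 CPM.
    """

    cpm_threshold: float = 15.0
    fdr_threshold: float = 0.05
    filter_rule: str = "min_group"
    test: str = "welch"

    def __post_init__(self) -> None:
        if self.cpm_threshold <= 0 or self.fdr_threshold <= 0:
            raise ValueError("thresholds must be > 0")
        if self.filter_rule not in ("min_group", "mean"):
            raise ValueError(f"unknown filter rule {self.filter_rule!r}")
        if self.test not in ("welch", "student"):
            raise ValueError(f"unknown test {self.test!r}")


@dataclass
class DifferentialResult:
    """Per-marker/per-gene effects, p-values and significance flags.

    ``table`` columns: ``effect`` (log2 fold change poor - good for counts;
    mean difference for scored markers), ``p``, ``fdr`` (equal to ``p``
    when no correction is applied), ``direction`` (up/down in the poor
    group), ``significant``.
    """

    table: pd.DataFrame
    layer: str  # score_panel | counts
    meta: dict = field(default_factory=dict)

    @property
    def significant_ids(self) -> pd.Index:
        return self.table.index[self.table["significant"].fillna(False)]

    def to_tsv(self, path) -> None:
        self.table.to_csv(path, sep="\t")


# -- score panel ---------------------------------------------------------


def compare_score_panel(
    panel: pd.DataFrame,
    groups: pd.Series,
    marker_kinds: Mapping[str, str] | None = None,
) -> DifferentialResult:
    """Compare each panel marker between prognosis groups.

    ``marker_kinds`` maps marker -> ``scored`` | ``binary``; markers whose
    values are all in {0, 1} default to ``binary``, others to ``scored``.
    Constant markers get an undefined p and a flag instead of an error.
    """
    groups = groups.reindex(panel.columns)
    if groups.isna().any():
        raise CohortError("group label missing for some panel subjects")
    good = panel.loc[:, groups == 0]
    poor = panel.loc[:, groups == 1]
    rows = []
    for name in panel.index:
        x, y = poor.loc[name].to_numpy(float), good.loc[name].to_numpy(float)
        kind = (marker_kinds or {}).get(name)
        if kind is None:
            kind = "binary" if set(np.unique(np.concatenate([x, y]))) <= {0.0, 1.0} else "scored"
        row = {"kind": kind, "mean_good": y.mean(), "mean_poor": x.mean(),
               "effect": x.mean() - y.mean()}
        try:
            if kind == "binary":
                tab = [[(y == 1).sum(), (y == 0).sum()], [(x == 1).sum(), (x == 0).sum()]]
                row["p"] = chisq_yates(tab).pvalue
            else:
                row["p"] = student_t_test(x, y).pvalue
            row["flagged"] = False
        except ValueError:
            row["p"] = np.nan
            row["flagged"] = True
        rows.append(pd.Series(row, name=name))
    table = pd.DataFrame(rows)
    table["fdr"] = table["p"]  # raw p reported; no multiplicity correction
    table["direction"] = np.where(table["effect"] >= 0, "up", "down")
    table["significant"] = table["p"] < 0.05
    return DifferentialResult(
        table=table, layer="score_panel", meta={"test": "student_t / yates_chisq", "correction": "none"}
    )


# -- count layer ---------------------------------------------------------


def cpm(counts: pd.DataFrame, library_sizes: pd.Series | None = None) -> pd.DataFrame:
    """Counts per million: count / library size x 1e6.

    Library sizes default to the column sums of ``counts``; pass the
    unfiltered sums explicitly when normalizing an already-filtered matrix.
    """
    lib = counts.sum(axis=0) if library_sizes is None else library_sizes.reindex(counts.columns)
    if (lib <= 0).any():
        bad = lib.index[lib <= 0].tolist()
        raise ValueError(f"zero library size for subjects: {bad[:5]}")
    return counts.div(lib, axis=1) * 1e6


def filter_low_expression(
    counts: pd.DataFrame,
    groups: pd.Series,
    config: DifferentialConfig | None = None,
) -> pd.DataFrame:
    """Drop low-expression genes; the filter is recomputed per cohort.

    Under ``min_group`` a gene survives if its CPM reaches the threshold in
    at least min(n_good, n_poor) subjects; under ``mean`` if its mean CPM
    does. Library sizes are the unfiltered column sums.
    """
    config = config or DifferentialConfig()
    groups = groups.reindex(counts.columns)
    if groups.isna().any():
        raise CohortError("group label missing for some count subjects")
    c = cpm(counts)
    if config.filter_rule == "min_group":
        n_min = int(min((groups == 0).sum(), (groups == 1).sum()))
        keep = (c >= config.cpm_threshold).sum(axis=1) >= n_min
    else:
        keep = c.mean(axis=1) >= config.cpm_threshold
    if not keep.any():
        raise ValueError("all genes removed by the expression filter")
    return counts.loc[keep]


def bh_adjust(p: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (monotone, capped at 1)."""
    p = np.asarray(p, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def differential_expression(
    counts: pd.DataFrame,
    groups: pd.Series,
    config: DifferentialConfig | None = None,
    library_sizes: pd.Series | None = None,
) -> DifferentialResult:
    """Per-gene differential expression, poor vs good prognosis.

    Input should already be expression-filtered (see
    :func:`filter_low_expression`); library sizes default to the column
    sums of the matrix handed in. Effect is the log2 fold change (mean
    log2(CPM + 0.5), poor minus good); p-values from a per-gene Welch
    t-test (Student optional), FDR by Benjamini-Hochberg.
    """
    config = config or DifferentialConfig()
    groups = groups.reindex(counts.columns)
    if groups.isna().any():
        raise CohortError("group label missing for some count subjects")
    n_good, n_poor = int((groups == 0).sum()), int((groups == 1).sum())
    if n_good < 2 or n_poor < 2:
        raise ValueError("need at least 2 subjects per group")
    logcpm = np.log2(cpm(counts, library_sizes) + 0.5)
    good = logcpm.loc[:, groups == 0].to_numpy()
    poor = logcpm.loc[:, groups == 1].to_numpy()
    stat, p = scipy.stats.ttest_ind(
        poor, good, axis=1, equal_var=(config.test == "student")
    )
    lfc = poor.mean(axis=1) - good.mean(axis=1)
    table = pd.DataFrame(
        {
            "effect": lfc,
            "p": p,
            "fdr": bh_adjust(np.nan_to_num(p, nan=1.0)),
            "direction": np.where(lfc >= 0, "up", "down"),
        },
        index=counts.index,
    )
    table["significant"] = table["fdr"] < config.fdr_threshold
    return DifferentialResult(
        table=table,
        layer="counts",
        meta={
            "test": config.test,
            "transform": "log2(CPM + 0.5)",
            "correction": "benjamini-hochberg",
            "fdr_threshold": config.fdr_threshold,
            "note": (
                "simple per-gene test substituting for moderated "
                "(voom/empirical-Bayes) pipelines"
            ),
            "n_good": n_good,
            "n_poor": n_poor,
        },
    )


# -- set comparison ------------------------------------------------------


@dataclass
class SetComparison:
    """Disjoint partition of significant markers across two analyses."""

    shared: list[str]
    pre_only: list[str]
    post_only: list[str]
    universe_size: int
    volcano: pd.DataFrame  # id, effect, minus_log10_p, category (pre & post)

    @property
    def counts(self) -> dict[str, int]:
        return {
            "shared": len(self.shared),
            "pre_only": len(self.pre_only),
            "post_only": len(self.post_only),
            "non_significant": self.universe_size
            - len(self.shared) - len(self.pre_only) - len(self.post_only),
        }

    def to_json(self) -> str:
        return json.dumps(
            {"counts": self.counts, "shared": self.shared,
             "pre_only": self.pre_only, "post_only": self.post_only},
            indent=2,
        )


def compare_sets(pre: DifferentialResult, post: DifferentialResult) -> SetComparison:
    """Compare significant sets before vs after matching.

    The universe is the intersection of the two retained marker/gene sets
    (the filter is recomputed post-matching, so the universes differ).
    Categories follow the four-way volcano convention: shared, pre-only,
    post-only, non-significant.
    """
    universe = pre.table.index.intersection(post.table.index)
    if len(universe) == 0:
        raise ValueError("no shared markers between the two results")
    pre_sig = set(pre.significant_ids) & set(universe)
    post_sig = set(post.significant_ids) & set(universe)
    shared = sorted(pre_sig & post_sig)
    pre_only = sorted(pre_sig - post_sig)
    post_only = sorted(post_sig - pre_sig)
    cat = pd.Series("non_significant", index=universe)
    cat[list(pre_only)] = "pre_only"
    cat[list(post_only)] = "post_only"
    cat[list(shared)] = "shared"
    with np.errstate(divide="ignore"):
        volcano = pd.DataFrame(
            {
                "effect_pre": pre.table.loc[universe, "effect"],
                "minus_log10_p_pre": -np.log10(pre.table.loc[universe, "p"]),
                "effect_post": post.table.loc[universe, "effect"],
                "minus_log10_p_post": -np.log10(post.table.loc[universe, "p"]),
                "category": cat,
            }
        )
    return SetComparison(
        shared=shared,
        pre_only=pre_only,
        post_only=post_only,
        universe_size=len(universe),
        volcano=volcano,
    )
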