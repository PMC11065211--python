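"""End-to-end orchestration: simulate/load -> score -> match -> balance ->
differential analysis -> set comparison.

Every stage writes its artifact to the output directory in a plain-text
format (TSV/JSON/markdown), and the final :class:`RunReport` only carries
numbers traceable to those artifacts. Identical config + seed produces
identical artifacts; plotting failures are logged, never fatal.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from . import cohort as cio
from .balance import BalanceTable, balance_table
from .cohort import Cohort
from .markers import (
    DifferentialConfig,
    SetComparison,
    compare_score_panel,
    compare_sets,
    differential_expression,
    filter_low_expression,
)
from .matching import MatchConfig, extract_matched_cohort, greedy_match
from .propensity import PropensityModel
from .simulate import CohortSpec, generate_cohort

logger = logging.getLogger("psmatch")

__all__ = ["PipelineConfig", "RunReport", "run_pipeline"]


@dataclass
class PipelineConfig:
    """Configuration of one pipeline run.

    Exactly one of ``cohort_path`` / ``simulate`` must be given. Covariate
    kinds come from the cohort file schema (``kinds``) or the simulation
    spec; ``covariates`` restricts the propensity model to a subset (the
    covariate list entered into the model is study-specific configuration).
    """

    output_dir: Path
    cohort_path: Path | None = None
    kinds: dict[str, str] = field(default_factory=dict)
    simulate: CohortSpec | None = None
    covariates: list[str] | None = None
    score_panel_path: Path | None = None
    counts_path: Path | None = None
    match: MatchConfig = field(default_factory=MatchConfig)
    differential: DifferentialConfig = field(default_factory=DifferentialConfig)
    seed: int = 0
    make_plots: bool = True

    def __post_init__(self) -> None:
        if (self.cohort_path is None) == (self.simulate is None):
            raise ValueError("give exactly one of cohort_path or simulate")


@dataclass
class RunReport:
    """Headline numbers of a run, each backed by an artifact file."""

    group_sizes_pre: tuple[int, int]
    group_sizes_post: tuple[int, int]
    n_pairs: int
    n_excluded: int
    balance: BalanceTable
    panel_summary: dict | None
    counts_summary: dict | None
    set_counts: dict | None
    provenance: dict

    def to_markdown(self) -> str:
        g0, p0 = self.group_sizes_pre
        g1, p1 = self.group_sizes_post
        lines = [
            "# Matching pipeline report",
            "",
            f"- groups before matching: good {g0} / poor {p0}",
            f"- groups after matching: good {g1} / poor {p1} "
            f"({self.n_pairs} matched sets, {self.n_excluded} focal cases excluded)",
            f"- caliper {self.provenance['caliper']} (probability scale, strict <), "
            f"ratio {self.provenance['ratio']}:1, seed {self.provenance['seed']}",
            "",
            "## Covariate balance",
            "",
            self.balance.to_markdown(),
        ]
        if self.panel_summary:
            lines += ["", "## Score panel",
                      "", f"- significant markers pre-matching: {self.panel_summary['n_sig_pre']}",
                      f"- significant markers post-matching: {self.panel_summary['n_sig_post']}"]
        if self.counts_summary:
            lines += ["", "## Count layer",
                      "", f"- genes retained pre / post: {self.counts_summary['n_genes_pre']}"
                      f" / {self.counts_summary['n_genes_post']}",
                      f"- significant genes (FDR < {self.provenance['fdr_threshold']}) "
                      f"pre / post: {self.counts_summary['n_sig_pre']}"
                      f" / {self.counts_summary['n_sig_post']}"]
        if self.set_counts:
            lines += ["", "## Significant-set comparison", "",
                      f"- shared: {self.set_counts['shared']}",
                      f"- pre-only: {self.set_counts['pre_only']}",
                      f"- post-only: {self.set_counts['post_only']}"]
        return "\n".join(lines) + "\n"


def _load_inputs(config: PipelineConfig) -> Cohort:
    if config.simulate is not None:
        cohort = generate_cohort(config.simulate)
    else:
        cohort = cio.read_cohort(config.cohort_path, kinds=config.kinds)
    if config.score_panel_path is not None:
        panel = cio.read_score_panel(config.score_panel_path)
        cohort.layers["score_panel"] = cio.align_layer_to_cohort(panel, cohort)
    if config.counts_path is not None:
        counts = cio.read_counts(config.counts_path)
        cohort.layers["counts"] = cio.align_layer_to_cohort(counts, cohort)
    return cohort


def run_pipeline(config: PipelineConfig) -> RunReport:
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)

    cohort = _load_inputs(config)
    logger.info("cohort: %d subjects (good %d / poor %d)",
                cohort.n_subjects, *cohort.group_sizes)
    cio.write_cohort(cohort, out / "cohort.tsv")
    for name, mat in cohort.layers.items():
        mat.to_csv(out / f"{name}.tsv", sep="\t")

    # propensity stage
    fit = PropensityModel.from_cohort(cohort, config.covariates).fit()
    scores = fit.score_cohort(cohort)
    (out / "propensity_model.json").write_text(json.dumps(fit.to_json_dict(), indent=2))
    pd.DataFrame(
        {"group": scores.groups, "propensity_score": scores.scores}
    ).rename_axis("subject_id").to_csv(out / "propensity_scores.tsv", sep="\t")

    # matching stage
    result = greedy_match(scores, config.match)
    logger.info("matching: focal group=%d, %d sets, %d excluded, %d unused",
                result.focal_group, result.n_pairs, len(result.excluded), len(result.unused))
    result.to_frame().to_csv(out / "match.tsv", sep="\t", index=False)
    matched = extract_matched_cohort(cohort, result)
    cio.write_cohort(matched, out / "matched_cohort.tsv")

    # balance stage
    bal = balance_table(cohort, matched)
    bal.table.to_csv(out / "balance.tsv", sep="\t", index=False)
    (out / "balance.md").write_text(bal.to_markdown())

    panel_summary = counts_summary = set_counts = None
    comparison: SetComparison | None = None

    if "score_panel" in cohort.layers:
        pre = compare_score_panel(cohort.layer("score_panel"), cohort.outcome)
        post = compare_score_panel(matched.layer("score_panel"), matched.outcome)
        pre.to_tsv(out / "panel_differential_pre.tsv")
        post.to_tsv(out / "panel_differential_post.tsv")
        comparison = compare_sets(pre, post)
        panel_summary = {
            "n_sig_pre": int(len(pre.significant_ids)),
            "n_sig_post": int(len(post.significant_ids)),
        }

    if "counts" in cohort.layers:
        counts = cohort.layer("counts")
        pre_f = filter_low_expression(counts, cohort.outcome, config.differential)
        pre = differential_expression(pre_f, cohort.outcome, config.differential)
        m_counts = matched.layer("counts")
        post_f = filter_low_expression(m_counts, matched.outcome, config.differential)
        post = differential_expression(post_f, matched.outcome, config.differential)
        pre.to_tsv(out / "counts_differential_pre.tsv")
        post.to_tsv(out / "counts_differential_post.tsv")
        comparison = compare_sets(pre, post)
        counts_summary = {
            "n_genes_pre": int(pre_f.shape[0]),
            "n_genes_post": int(post_f.shape[0]),
            "n_sig_pre": int(len(pre.significant_ids)),
            "n_sig_post": int(len(post.significant_ids)),
        }

    if comparison is not None:
        (out / "set_comparison.json").write_text(comparison.to_json())
        comparison.volcano.rename_axis("id").to_csv(out / "volcano.tsv", sep="\t")
        set_counts = comparison.counts

    if config.make_plots:
        try:
            from . import plots

            plots.plot_score_distribution(scores, out / "score_distribution.png")
            if comparison is not None:
                plots.plot_set_counts(comparison, out / "set_counts.png")
                if counts_summary is not None:
                    plots.plot_volcano(comparison, "post", out / "volcano.png")
        except Exception:  # plotting must never fail the pipeline
            logger.exception("plotting failed; continuing")

    report = RunReport(
        group_sizes_pre=cohort.group_sizes,
        group_sizes_post=matched.group_sizes,
        n_pairs=result.n_pairs,
        n_excluded=len(result.excluded),
        balance=bal,
        panel_summary=panel_summary,
        counts_summary=counts_summary,
        set_counts=set_counts,
        provenance={
            "seed": config.seed if config.simulate is None else config.simulate.seed,
            "caliper": config.match.caliper,
            "ratio": config.match.ratio,
            "filter_rule": config.differential.filter_rule,
            "cpm_threshold": config.differential.cpm_threshold,
            "fdr_threshold": config.differential.fdr_threshold,
            "test": config.differential.test,
        },
    )
    (out / "report.md").write_text(report.to_markdown())
    return report
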