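"""Reference contingency tables from published colorectal-cancer cohorts.

Two prognosis cohorts (good vs poor outcome at three years) as publicly
printed in their clinicopathological summary tables: an
immunohistochemistry cohort of 427 subjects (367 good / 60 poor, matched
down to 58 per group) and an RNA-seq cohort of 163 subjects (130 / 33,
matched to 28 per group). Each entry is a 2x2 table of per-level counts
(rows: good, poor; columns: the two covariate levels) with the p-value
printed alongside it, so the package's Yates-corrected chi-squared can be
checked against independently typeset values.

The post-matching "location" row of the IHC cohort is omitted: its printed
p-value is inconsistent with its printed counts (a typesetting error) and
cannot serve as a reference.
"""

from __future__ import annotations

from typing import NamedTuple

__all__ = ["ReferenceTable", "IHC_COHORT_TABLES", "RNASEQ_COHORT_TABLES", "all_reference_tables"]


class ReferenceTable(NamedTuple):
    name: str
    counts: tuple[tuple[int, int], tuple[int, int]]  # rows good/poor
    printed_p: float
    decimals: int  # precision at which the p-value was printed


#: IHC cohort, 367 good / 60 poor before matching, 58 / 58 after.
IHC_COHORT_TABLES: tuple[ReferenceTable, ...] = (
    ReferenceTable("ihc_gender_pre", ((175, 192), (39, 21)), 0.01889, 5),
    ReferenceTable("ihc_location_pre", ((183, 184), (23, 37)), 0.1291, 4),
    ReferenceTable("ihc_mmr_pre", ((87, 280), (10, 50)), 0.2982, 4),
    ReferenceTable("ihc_histology_pre", ((25, 342), (5, 55)), 0.8768, 4),
    ReferenceTable("ihc_gender_post", ((32, 26), (38, 20)), 0.3426, 4),
    ReferenceTable("ihc_mmr_post", ((7, 51), (10, 48)), 0.5995, 4),
    ReferenceTable("ihc_histology_post", ((5, 53), (5, 53)), 1.0, 4),
    ReferenceTable("ihc_lymphatic_post", ((26, 32), (25, 33)), 1.0, 4),
    ReferenceTable("ihc_perineural_post", ((13, 45), (13, 45)), 1.0, 4),
)

#: RNA-seq cohort, 130 good / 33 poor before matching, 28 / 28 after.
RNASEQ_COHORT_TABLES: tuple[ReferenceTable, ...] = (
    ReferenceTable("rnaseq_gender_pre", ((72, 58), (19, 14)), 0.976, 3),
    ReferenceTable("rnaseq_mmr_pre", ((10, 120), (0, 33)), 0.2156, 4),
    ReferenceTable("rnaseq_histology_pre", ((9, 121), (8, 25)), 0.0096, 4),
    ReferenceTable("rnaseq_venous_pre", ((22, 108), (13, 20)), 0.010, 3),
    ReferenceTable("rnaseq_lymphatic_pre", ((32, 98), (16, 17)), 0.013, 3),
    ReferenceTable("rnaseq_perineural_pre", ((9, 121), (7, 26)), 0.033, 3),
    ReferenceTable("rnaseq_gender_post", ((17, 11), (16, 12)), 1.0, 4),
    ReferenceTable("rnaseq_histology_post", ((6, 22), (7, 21)), 1.0, 4),
    ReferenceTable("rnaseq_residual_post", ((8, 20), (10, 18)), 0.7748, 4),
    ReferenceTable("rnaseq_lymphatic_post", ((10, 18), (12, 16)), 0.7844, 4),
    ReferenceTable("rnaseq_venous_post", ((10, 18), (9, 19)), 1.0, 4),
    ReferenceTable("rnaseq_perineural_post", ((4, 24), (3, 25)), 1.0, 4),
)


def all_reference_tables() -> tuple[ReferenceTable, ...]:
    return IHC_COHORT_TABLES + RNASEQ_COHORT_TABLES
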