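"""Subject-level cohort container and file I/O.

A :class:`Cohort` holds one row per subject: clinicopathological covariates,
a binary prognosis label (1 = poor outcome, 0 = good outcome), and optional
marker layers — an immunohistochemistry-style score panel (markers x
subjects) and/or an RNA-seq count matrix (genes x subjects).

Cohort tables travel as TSV/CSV; count matrices as TSV or MatrixMarket with
plain-text row/column sidecars.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse

__all__ = [
    "Cohort",
    "CohortError",
    "read_cohort",
    "write_cohort",
    "read_counts",
    "write_counts",
    "read_score_panel",
    "write_score_panel",
]

#: covariate kinds a cohort understands
COVARIATE_KINDS = ("continuous", "binary", "ordinal")

#: labels merged into the positive level of a binary covariate on ingest
DEFAULT_POSITIVE_LABELS = frozenset({"positive", "present", "yes", "1", "true"})


class CohortError(ValueError):
    """Raised for malformed cohort inputs (duplicate ids, missing values...)."""


@dataclass
class Cohort:
    """Subject-level study cohort.

    Parameters
    ----------
    covariates
        Subjects x covariates table, indexed by unique subject id.
    outcome
        Binary prognosis label per subject; 1 = poor prognosis, 0 = good.
    kinds
        Map covariate name -> one of ``continuous | binary | ordinal``.
        Ordinal covariates (e.g. TNM stage, tumor differentiation) are coded
        as their integer grade and treated numerically.
    layers
        Optional marker matrices keyed by layer name (``score_panel``,
        ``counts``); columns are subject ids.
    """

    covariates: pd.DataFrame
    outcome: pd.Series
    kinds: Mapping[str, str]
    layers: dict[str, pd.DataFrame] = field(default_factory=dict)

    def __post_init__(self) -> None:
        ids = self.covariates.index
        if ids.has_duplicates:
            dupes = ids[ids.duplicated()].unique().tolist()
            raise CohortError(f"duplicate subject ids: {dupes}")
        if self.covariates.isna().any().any():
            bad = self.covariates.columns[self.covariates.isna().any()].tolist()
            raise CohortError(f"missing covariate values in columns: {bad}")
        self.outcome = self.outcome.reindex(ids)
        if self.outcome.isna().any():
            raise CohortError("outcome missing for some subjects")
        self.outcome = self.outcome.astype(int)
        if not set(self.outcome.unique()) <= {0, 1}:
            raise CohortError("outcome must be coded 0 (good) / 1 (poor)")
        for name in self.kinds:
            if name not in self.covariates.columns:
                raise CohortError(f"kind declared for unknown covariate {name!r}")
            if self.kinds[name] not in COVARIATE_KINDS:
                raise CohortError(f"unknown covariate kind {self.kinds[name]!r}")
        for layer_name, mat in self.layers.items():
            missing = [s for s in mat.columns if s not in ids]
            if missing:
                raise CohortError(
                    f"layer {layer_name!r} has subjects absent from the cohort: {missing[:5]}"
                )

    # -- basic queries -------------------------------------------------

    @property
    def subject_ids(self) -> pd.Index:
        return self.covariates.index

    @property
    def n_subjects(self) -> int:
        return len(self.covariates)

    @property
    def group_sizes(self) -> tuple[int, int]:
        """(n good, n poor)."""
        return int((self.outcome == 0).sum()), int((self.outcome == 1).sum())

    def subset(self, ids) -> "Cohort":
        """Sub-cohort restricted to ``ids`` (order preserved), layers included."""
        ids = pd.Index(ids)
        unknown = ids.difference(self.subject_ids)
        if len(unknown):
            raise CohortError(f"unknown subject ids: {unknown.tolist()[:5]}")
        layers = {
            name: mat.loc[:, [i for i in ids if i in mat.columns]]
            for name, mat in self.layers.items()
        }
        return Cohort(
            covariates=self.covariates.loc[ids],
            outcome=self.outcome.loc[ids],
            kinds=dict(self.kinds),
            layers=layers,
        )

    def layer(self, name: str) -> pd.DataFrame:
        try:
            return self.layers[name]
        except KeyError:
            raise CohortError(f"cohort has no marker layer {name!r}") from None


# -- cohort table I/O ----------------------------------------------------


def _sep_for(path: Path) -> str:
    return "," if path.suffix.lower() == ".csv" else "\t"


def read_cohort(
    path,
    kinds: Mapping[str, str],
    outcome_col: str = "outcome",
    id_col: str = "subject_id",
    positive_labels: frozenset = DEFAULT_POSITIVE_LABELS,
) -> Cohort:
    """Read a cohort table from TSV or CSV.

    String-valued binary covariates are recoded 0/1 on ingest: values whose
    lowercased form is in ``positive_labels`` become 1, everything else —
    including "unknown"/"absent" style levels — is merged into the
    negative/reference level 0.
    """
    path = Path(path)
    df = pd.read_csv(path, sep=_sep_for(path))
    if id_col not in df.columns:
        raise CohortError(f"missing id column {id_col!r}")
    if outcome_col not in df.columns:
        raise CohortError(f"missing outcome column {outcome_col!r}")
    if df[id_col].duplicated().any():
        dupes = df.loc[df[id_col].duplicated(), id_col].tolist()
        raise CohortError(f"duplicate subject ids: {dupes}")
    df = df.set_index(id_col)
    outcome = df.pop(outcome_col)
    covs = df[[c for c in df.columns if c in kinds]].copy()
    for name, kind in kinds.items():
        if name not in covs.columns:
            raise CohortError(f"covariate {name!r} not found in {path.name}")
        col = covs[name]
        if kind == "binary" and col.dtype == object:
            covs[name] = (
                col.astype(str).str.strip().str.lower().isin(positive_labels).astype(int)
            )
        else:
            try:
                covs[name] = pd.to_numeric(col)
            except (TypeError, ValueError) as exc:
                raise CohortError(f"unparseable values in covariate {name!r}") from exc
    return Cohort(covariates=covs, outcome=outcome, kinds=dict(kinds))


def write_cohort(cohort: Cohort, path) -> None:
    path = Path(path)
    out = cohort.covariates.copy()
    out["outcome"] = cohort.outcome
    out.index.name = "subject_id"
    out.to_csv(path, sep=_sep_for(path))


# -- marker matrix I/O ---------------------------------------------------


def read_counts(path) -> pd.DataFrame:
    """Read a genes x subjects count matrix.

    Accepts TSV (gene ids in the first column, subject ids as header) or
    MatrixMarket ``.mtx`` with ``<stem>.rows`` / ``<stem>.cols`` sidecars
    (one id per line). Counts must be non-negative integers.
    """
    path = Path(path)
    if path.suffix == ".mtx":
        mat = scipy.io.mmread(path)
        if scipy.sparse.issparse(mat):
            mat = mat.toarray()
        rows = Path(str(path) + ".rows").read_text().split()
        cols = Path(str(path) + ".cols").read_text().split()
        df = pd.DataFrame(mat, index=rows, columns=cols)
    else:
        df = pd.read_csv(path, sep=_sep_for(path), index_col=0)
    if df.shape[0] == 0:
        raise CohortError(f"empty gene set in {path.name}")
    if df.index.has_duplicates:
        raise CohortError("duplicate gene ids")
    vals = df.to_numpy()
    if np.any(vals < 0) or not np.allclose(vals, np.round(vals)):
        raise CohortError("counts must be non-negative integers")
    return df.round().astype(np.int64)


def write_counts(counts: pd.DataFrame, path) -> None:
    """Write counts as TSV, or as MatrixMarket + sidecars for ``.mtx`` paths."""
    path = Path(path)
    if path.suffix == ".mtx":
        scipy.io.mmwrite(str(path), scipy.sparse.coo_matrix(counts.to_numpy()))
        Path(str(path) + ".rows").write_text("\n".join(map(str, counts.index)) + "\n")
        Path(str(path) + ".cols").write_text("\n".join(map(str, counts.columns)) + "\n")
    else:
        counts.to_csv(path, sep=_sep_for(path))


def read_score_panel(path) -> pd.DataFrame:
    """Read a markers x subjects score-panel TSV (marker ids in column one)."""
    path = Path(path)
    df = pd.read_csv(path, sep=_sep_for(path), index_col=0)
    if df.index.has_duplicates:
        raise CohortError("duplicate marker ids")
    return df


def write_score_panel(panel: pd.DataFrame, path) -> None:
    panel.to_csv(Path(path), sep="\t")


def align_layer_to_cohort(layer: pd.DataFrame, cohort: Cohort) -> pd.DataFrame:
    """Reorder a marker matrix's columns to cohort subject order, by id."""
    missing = cohort.subject_ids.difference(layer.columns)
    if len(missing):
        raise CohortError(f"marker matrix lacks subjects: {missing.tolist()[:5]}")
    return layer.loc[:, cohort.subject_ids]


def cohort_schema_json(cohort: Cohort) -> str:
    """Serializable description of the cohort schema (for run reports)."""
    return json.dumps(
        {
            "n_subjects": cohort.n_subjects,
            "group_sizes": {"good": cohort.group_sizes[0], "poor": cohort.group_sizes[1]},
            "covariates": dict(cohort.kinds),
            "layers": {k: list(v.shape) for k, v in cohort.layers.items()},
        },
        indent=2,
    )
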