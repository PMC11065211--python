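"""Synthetic confounded-cohort generator.

Emulates the structure of a prognosis biomarker study: clinicopathological
covariates (continuous, binary, ordinal), a binary outcome drawn from a
logistic model on those covariates — so confounding exists by construction
— and marker layers with known truth:

* a *score panel* of bounded immunohistochemistry-style scores (weighted
  0-300 scores, percent-positive 0-100 scores, or binary calls), and
* a *counts* layer of negative-binomial RNA-seq-like gene counts with
  log-normal library sizes.

Marker values may depend on the outcome directly (``prognostic_effect``, a
genuinely prognostic marker), on covariates (``confounder_loadings``, a
spurious marker whenever the loaded covariate also drives the outcome), on
neither (a null marker), or on both. Confounder loadings are applied to
*standardized* covariates so a loading of c means "c units of marker signal
per SD of the covariate"; count-layer effects are on the log2 scale.

All randomness flows from a single integer seed through per-layer
:class:`numpy.random.SeedSequence` sub-streams, so cohorts are bit-identical
across runs for a given spec.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.special import expit

from .cohort import Cohort

__all__ = [
    "CovariateSpec",
    "MarkerSpec",
    "CohortSpec",
    "DegenerateOutcomeError",
    "generate_cohort",
    "confounded_marker_scenario",
    "spec_from_dict",
]


class DegenerateOutcomeError(RuntimeError):
    """All simulated subjects fell in one outcome class."""


@dataclass(frozen=True)
class CovariateSpec:
    """One simulated clinicopathological covariate.

    ``outcome_coefficient`` is the covariate's contribution to the
    poor-prognosis log-odds per raw unit (continuous/ordinal) or for the
    positive level (binary); a nonzero value makes the covariate a
    confounder candidate.
    """

    name: str
    kind: str  # continuous | binary | ordinal
    mean: float | None = None
    sd: float | None = None
    prevalence: float | None = None
    probs: tuple[float, ...] | None = None  # ordinal levels 1..K
    outcome_coefficient: float = 0.0

    def __post_init__(self) -> None:
        if self.kind == "continuous":
            if self.mean is None or self.sd is None or self.sd <= 0:
                raise ValueError(f"{self.name}: continuous needs mean and sd > 0")
        elif self.kind == "binary":
            if self.prevalence is None or not 0 <= self.prevalence <= 1:
                raise ValueError(f"{self.name}: binary needs prevalence in [0, 1]")
        elif self.kind == "ordinal":
            if self.probs is None or any(p < 0 for p in self.probs):
                raise ValueError(f"{self.name}: ordinal needs non-negative probs")
            if not math.isclose(sum(self.probs), 1.0, abs_tol=1e-9):
                raise ValueError(f"{self.name}: ordinal probs must sum to 1")
        else:
            raise ValueError(f"{self.name}: unknown kind {self.kind!r}")

    @property
    def marginal_mean(self) -> float:
        if self.kind == "continuous":
            return float(self.mean)
        if self.kind == "binary":
            return float(self.prevalence)
        levels = np.arange(1, len(self.probs) + 1)
        return float(np.dot(levels, self.probs))

    @property
    def marginal_sd(self) -> float:
        if self.kind == "continuous":
            return float(self.sd)
        if self.kind == "binary":
            p = self.prevalence
            return float(math.sqrt(max(p * (1 - p), 1e-12)))
        levels = np.arange(1, len(self.probs) + 1)
        m = self.marginal_mean
        return float(math.sqrt(max(np.dot((levels - m) ** 2, self.probs), 1e-12)))


@dataclass(frozen=True)
class MarkerSpec:
    """One simulated marker (score-panel entry or gene).

    For ``layer="score_panel"``: value = baseline + prognostic_effect * Z +
    sum(loading * standardized covariate) + Gaussian noise, clipped to
    ``score_range``; ``binary_cutpoint`` instead thresholds the latent value
    into a negative/positive call.

    For ``layer="counts"``: counts are negative-binomial with
    log2 mean = log2(baseline_mean * library factor) + prognostic_effect * Z
    + sum(loading * standardized covariate), i.e. ``prognostic_effect`` is a
    log2 fold change, and ``dispersion`` the NB dispersion (1/size).
    """

    name: str
    layer: str  # score_panel | counts
    prognostic_effect: float = 0.0
    confounder_loadings: Mapping[str, float] = field(default_factory=dict)
    # score-panel parameters
    baseline: float = 0.0
    noise_sd: float = 1.0
    score_range: tuple[float, float] = (0.0, 300.0)
    binary_cutpoint: float | None = None
    # counts parameters
    baseline_mean: float = 100.0
    dispersion: float = 0.1

    def __post_init__(self) -> None:
        if self.layer not in ("score_panel", "counts"):
            raise ValueError(f"{self.name}: unknown layer {self.layer!r}")
        if self.layer == "score_panel":
            lo, hi = self.score_range
            if not hi > lo:
                raise ValueError(f"{self.name}: degenerate score range")
            if self.noise_sd <= 0:
                raise ValueError(f"{self.name}: noise sd must be > 0")
        else:
            if self.baseline_mean <= 0 or self.dispersion <= 0:
                raise ValueError(f"{self.name}: NB mean and dispersion must be > 0")


@dataclass(frozen=True)
class CohortSpec:
    """Full recipe for one synthetic cohort."""

    n_subjects: int
    outcome_intercept: float
    covariates: tuple[CovariateSpec, ...]
    markers: tuple[MarkerSpec, ...] = ()
    seed: int = 0
    library_size_sigma: float = 0.2  # log-normal spread of count library factors

    def __post_init__(self) -> None:
        if self.n_subjects < 2:
            raise ValueError("n_subjects must be >= 2")
        if not self.covariates:
            raise ValueError("at least one covariate required")


def _draw_covariates(spec: CohortSpec, rng: np.random.Generator) -> pd.DataFrame:
    cols = {}
    for cov in spec.covariates:
        if cov.kind == "continuous":
            cols[cov.name] = rng.normal(cov.mean, cov.sd, spec.n_subjects)
        elif cov.kind == "binary":
            cols[cov.name] = rng.binomial(1, cov.prevalence, spec.n_subjects)
        else:
            levels = np.arange(1, len(cov.probs) + 1)
            cols[cov.name] = rng.choice(levels, size=spec.n_subjects, p=cov.probs)
    ids = pd.Index([f"S{i:05d}" for i in range(spec.n_subjects)], name="subject_id")
    return pd.DataFrame(cols, index=ids)


def _standardized(cov_table: pd.DataFrame, spec: CohortSpec) -> pd.DataFrame:
    out = {}
    for cov in spec.covariates:
        out[cov.name] = (cov_table[cov.name] - cov.marginal_mean) / cov.marginal_sd
    return pd.DataFrame(out, index=cov_table.index)


def generate_cohort(spec: CohortSpec) -> Cohort:
    """Draw one cohort from ``spec``; bit-identical for identical spec + seed.

    Raises
    ------
    DegenerateOutcomeError
        If the simulated outcome has a single class; adjust
        ``outcome_intercept`` or use another seed.
    """
    ss = np.random.SeedSequence(spec.seed)
    cov_ss, out_ss, panel_ss, count_ss, lib_ss = ss.spawn(5)

    cov_table = _draw_covariates(spec, np.random.default_rng(cov_ss))

    lin = np.full(spec.n_subjects, spec.outcome_intercept, dtype=float)
    for cov in spec.covariates:
        lin += cov.outcome_coefficient * cov_table[cov.name].to_numpy(dtype=float)
    outcome = np.random.default_rng(out_ss).binomial(1, expit(lin))
    if outcome.min() == outcome.max():
        raise DegenerateOutcomeError(
            "simulated outcome is single-class; adjust outcome_intercept "
            f"(got all {'poor' if outcome[0] else 'good'}) or change the seed"
        )
    z = pd.Series(outcome, index=cov_table.index, name="outcome")

    std = _standardized(cov_table, spec)
    layers: dict[str, pd.DataFrame] = {}

    panel_specs = [m for m in spec.markers if m.layer == "score_panel"]
    if panel_specs:
        rng = np.random.default_rng(panel_ss)
        rows = {}
        for m in panel_specs:
            latent = m.baseline + m.prognostic_effect * outcome
            for cov_name, loading in m.confounder_loadings.items():
                latent = latent + loading * std[cov_name].to_numpy()
            latent = latent + rng.normal(0.0, m.noise_sd, spec.n_subjects)
            if m.binary_cutpoint is not None:
                rows[m.name] = (latent >= m.binary_cutpoint).astype(float)
            else:
                rows[m.name] = np.clip(latent, *m.score_range)
        layers["score_panel"] = pd.DataFrame.from_dict(
            rows, orient="index", columns=cov_table.index
        )

    count_specs = [m for m in spec.markers if m.layer == "counts"]
    if count_specs:
        lib = np.random.default_rng(lib_ss).lognormal(
            mean=-spec.library_size_sigma**2 / 2,
            sigma=spec.library_size_sigma,
            size=spec.n_subjects,
        )  # mean-1 multiplicative library factors
        rng = np.random.default_rng(count_ss)
        rows = {}
        for m in count_specs:
            log2mu = np.log2(m.baseline_mean * lib) + m.prognostic_effect * outcome
            for cov_name, loading in m.confounder_loadings.items():
                log2mu = log2mu + loading * std[cov_name].to_numpy()
            mu = np.exp2(log2mu)
            size = 1.0 / m.dispersion
            rows[m.name] = rng.negative_binomial(size, size / (size + mu))
        layers["counts"] = pd.DataFrame.from_dict(
            rows, orient="index", columns=cov_table.index
        ).astype(np.int64)

    kinds = {c.name: c.kind for c in spec.covariates}
    return Cohort(covariates=cov_table, outcome=z, kinds=kinds, layers=layers)


# -- the tuned confounded scenario --------------------------------------

#: age effect on the poor-prognosis log-odds, per year; calibrated so the
#: realized poor-vs-good age gap is about -8 years (a younger poor group),
#: the magnitude typical of prognosis cohorts of this kind.
_AGE_COEF = -0.071
#: TNM stage effect per grade; makes stage the dominant confounder.
_STAGE_COEF = 0.80
#: intercept giving a poor-group fraction near 0.20 at these covariates.
_INTERCEPT = -(_AGE_COEF * 64.0) - _STAGE_COEF * 2.5 - 1.40


def scenario_spec(seed: int, n_subjects: int = 400) -> CohortSpec:
    """Spec of the canonical confounded-marker scenario (see below)."""
    covariates = (
        CovariateSpec("age", "continuous", mean=64.0, sd=12.0,
                      outcome_coefficient=_AGE_COEF),
        CovariateSpec("gender_male", "binary", prevalence=0.50),
        CovariateSpec("tnm_stage", "ordinal", probs=(0.20, 0.30, 0.30, 0.20),
                      outcome_coefficient=_STAGE_COEF),
        CovariateSpec("lymphatic_invasion", "binary", prevalence=0.25),
    )
    markers = (
        MarkerSpec("TRUE_PROG", "score_panel", prognostic_effect=25.0,
                   baseline=120.0, noise_sd=30.0, score_range=(0.0, 300.0)),
        MarkerSpec("SPURIOUS_STAGE", "score_panel", prognostic_effect=0.0,
                   confounder_loadings={"tnm_stage": 30.0},
                   baseline=120.0, noise_sd=30.0, score_range=(0.0, 300.0)),
        MarkerSpec("NULL_MARKER", "score_panel", prognostic_effect=0.0,
                   baseline=120.0, noise_sd=30.0, score_range=(0.0, 300.0)),
    )
    return CohortSpec(
        n_subjects=n_subjects,
        outcome_intercept=_INTERCEPT,
        covariates=covariates,
        markers=markers,
        seed=seed,
    )


def confounded_marker_scenario(
    seed: int, n_subjects: int = 400
) -> tuple[Cohort, dict[str, str]]:
    """Generate the canonical confounded cohort with known marker truth.

    The scenario builds the failure mode propensity matching is designed to
    fix: ``SPURIOUS_STAGE`` tracks TNM stage, which also drives the outcome,
    so it separates the prognosis groups before matching despite having no
    prognostic effect of its own. ``TRUE_PROG`` shifts with the outcome
    only; ``NULL_MARKER`` with nothing.

    Returns the cohort and a truth map
    ``{marker name: "true" | "spurious" | "null"}``.
    """
    cohort = generate_cohort(scenario_spec(seed, n_subjects))
    truth = {
        "TRUE_PROG": "true",
        "SPURIOUS_STAGE": "spurious",
        "NULL_MARKER": "null",
    }
    return cohort, truth


# -- config-file plumbing ------------------------------------------------


def spec_from_dict(d: Mapping) -> CohortSpec:
    """Build a :class:`CohortSpec` from a parsed YAML/JSON mapping."""
    covs = tuple(
        CovariateSpec(
            name=c["name"],
            kind=c["kind"],
            mean=c.get("mean"),
            sd=c.get("sd"),
            prevalence=c.get("prevalence"),
            probs=tuple(c["probs"]) if "probs" in c else None,
            outcome_coefficient=c.get("outcome_coefficient", 0.0),
        )
        for c in d["covariates"]
    )
    markers = tuple(
        MarkerSpec(
            name=m["name"],
            layer=m["layer"],
            prognostic_effect=m.get("prognostic_effect", 0.0),
            confounder_loadings=dict(m.get("confounder_loadings", {})),
            baseline=m.get("baseline", 0.0),
            noise_sd=m.get("noise_sd", 1.0),
            score_range=tuple(m.get("score_range", (0.0, 300.0))),
            binary_cutpoint=m.get("binary_cutpoint"),
            baseline_mean=m.get("baseline_mean", 100.0),
            dispersion=m.get("dispersion", 0.1),
        )
        for m in d.get("markers", [])
    )
    return CohortSpec(
        n_subjects=int(d["n_subjects"]),
        outcome_intercept=float(d.get("outcome_intercept", 0.0)),
        covariates=covs,
        markers=markers,
        seed=int(d.get("seed", 0)),
        library_size_sigma=float(d.get("library_size_sigma", 0.2)),
    )
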