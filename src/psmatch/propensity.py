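"""Propensity-score estimation by maximum-likelihood logistic regression.

The propensity score e(x_i) = Pr(Z_i = 1 | x_i) is the modeled probability
that subject i belongs to the poor-prognosis group given their
clinicopathological covariates x_i. It is estimated with a plain binomial
logit model

    ln e(x_i) / (1 - e(x_i)) = b0 + b1 x_i1 + ... + bk x_ik

fitted by IRLS (no regularization; perfect separation is reported as an
error, never silently penalized), and scores are the logistic transform of
the fitted linear predictor — the ``predict(type="response")`` convention.

The surface follows the Model/Results idiom: build a
:class:`PropensityModel` from a cohort, call :meth:`~PropensityModel.fit`,
and use the returned :class:`PropensityResults` to score subjects, match
groups and summarize the fit.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy.special import expit

from .cohort import Cohort, CohortError

__all__ = [
    "PropensityModel",
    "PropensityResults",
    "PropensityScores",
    "ScoreDistribution",
    "SeparationError",
    "SingularDesignError",
    "score_distribution_summary",
]


class SeparationError(RuntimeError):
    """The logit MLE does not exist: covariates separate the outcome."""


class SingularDesignError(RuntimeError):
    """The design matrix is rank deficient (collinear covariates)."""


@dataclass
class PropensityScores:
    """Per-subject propensity scores with group labels.

    ``scores`` are strictly inside (0, 1); ``groups`` is the binary
    prognosis label (1 = poor) aligned on the same subject index.
    """

    scores: pd.Series
    groups: pd.Series

    def __post_init__(self) -> None:
        self.groups = self.groups.reindex(self.scores.index)
        if self.groups.isna().any():
            raise ValueError("group label missing for some scored subjects")
        s = self.scores.to_numpy(dtype=float)
        if np.any(s <= 0.0) or np.any(s >= 1.0):
            raise ValueError("propensity scores must lie strictly in (0, 1)")

    def by_group(self) -> tuple[pd.Series, pd.Series]:
        """(scores of good-prognosis group, scores of poor-prognosis group)."""
        return self.scores[self.groups == 0], self.scores[self.groups == 1]


class PropensityModel:
    """Binomial logit model of poor-prognosis membership on covariates."""

    def __init__(self, outcome: pd.Series, exog: pd.DataFrame):
        if exog.isna().any().any():
            raise CohortError("missing values in model covariates")
        counts = outcome.value_counts()
        if counts.get(0, 0) < 2 or counts.get(1, 0) < 2:
            raise CohortError("need at least 2 subjects per outcome class")
        self.outcome = outcome.astype(float)
        self.exog = exog.astype(float)
        self.covariate_names = list(exog.columns)
        self._design = sm.add_constant(self.exog, prepend=True, has_constant="add")
        self._check_separation()
        self._check_rank()

    @classmethod
    def from_cohort(cls, cohort: Cohort, covariate_names: list[str] | None = None):
        """Build the model from a cohort; defaults to all cohort covariates.

        Binary covariates are coded 0/1 and ordinal covariates enter as
        their integer grade (TNM stage 1-4 etc.), i.e. every covariate is
        treated numerically.
        """
        names = list(cohort.kinds) if covariate_names is None else list(covariate_names)
        missing = [n for n in names if n not in cohort.covariates.columns]
        if missing:
            raise CohortError(f"covariates not in cohort: {missing}")
        return cls(cohort.outcome, cohort.covariates[names])

    # single-covariate complete separation: one group's values all above
    # the other's — the MLE diverges along that coordinate
    def _check_separation(self) -> None:
        y = self.outcome.to_numpy()
        separating = []
        for name in self.covariate_names:
            x = self.exog[name].to_numpy()
            x1, x0 = x[y == 1], x[y == 0]
            if len(x1) and len(x0) and (x1.min() > x0.max() or x0.min() > x1.max()):
                separating.append(name)
        if separating:
            raise SeparationError(
                f"perfect separation by covariate(s) {separating}; "
                "the logistic MLE does not exist"
            )

    def _check_rank(self) -> None:
        X = self._design.to_numpy()
        rank = np.linalg.matrix_rank(X)
        if rank < X.shape[1]:
            from scipy.linalg import qr

            _, _, piv = qr(X, pivoting=True, mode="economic")
            dropped = [self._design.columns[i] for i in sorted(piv[rank:])]
            raise SingularDesignError(
                f"design matrix is singular; collinear column(s): {dropped}"
            )

    def fit(self, maxiter: int = 100, tol: float = 1e-8) -> "PropensityResults":
        """Fit by IRLS; ``tol`` is the relative convergence tolerance."""
        glm = sm.GLM(self.outcome, self._design, family=sm.families.Binomial())
        res = glm.fit(maxiter=maxiter, tol=tol)
        params = res.params
        if not np.all(np.isfinite(params)):
            raise SeparationError("non-finite coefficients; likely separation")
        fitted = np.asarray(res.fittedvalues)
        if fitted.min() < 1e-10 or fitted.max() > 1 - 1e-10:
            # quasi-separation missed by the single-covariate screen
            extreme = np.abs(params[1:]) > 25
            names = [n for n, e in zip(self.covariate_names, extreme) if e]
            if names:
                raise SeparationError(
                    f"fitted probabilities degenerate; suspect separation by {names}"
                )
        return PropensityResults(self, res)


class PropensityResults:
    """Fitted propensity model: coefficients, uncertainty and scoring."""

    def __init__(self, model: PropensityModel, glm_results):
        self.model = model
        self._res = glm_results

    @property
    def params(self) -> pd.Series:
        """Intercept b0 (named ``const``) and coefficients b_i."""
        return self._res.params

    @property
    def intercept(self) -> float:
        return float(self._res.params["const"])

    @property
    def coefficients(self) -> pd.Series:
        return self._res.params.drop("const")

    @property
    def bse(self) -> pd.Series:
        return self._res.bse

    @property
    def llf(self) -> float:
        return float(self._res.llf)

    @property
    def converged(self) -> bool:
        return bool(self._res.converged)

    @property
    def n_iter(self) -> int:
        return int(self._res.fit_history["iteration"])

    def linear_predictor(self, covariates: pd.DataFrame) -> pd.Series:
        missing = [n for n in self.model.covariate_names if n not in covariates]
        if missing:
            raise CohortError(f"covariates missing at scoring time: {missing}")
        X = covariates[self.model.covariate_names].astype(float)
        eta = self.intercept + X.to_numpy() @ self.coefficients.to_numpy()
        return pd.Series(eta, index=covariates.index, name="linear_predictor")

    def predict(self, covariates: pd.DataFrame) -> pd.Series:
        """Propensity scores e(x) = logistic(b0 + b^T x), in (0, 1)."""
        return expit(self.linear_predictor(covariates)).rename("propensity_score")

    def score_cohort(self, cohort: Cohort) -> PropensityScores:
        return PropensityScores(
            scores=self.predict(cohort.covariates), groups=cohort.outcome
        )

    def summary(self) -> str:
        head = (
            f"Propensity logit fit: n={len(self.model.outcome)}, "
            f"converged={self.converged}, iterations={self.n_iter}, "
            f"log-likelihood={self.llf:.4f}\n"
        )
        tab = pd.DataFrame({"coef": self.params, "std err": self.bse})
        tab["z"] = tab["coef"] / tab["std err"]
        return head + tab.to_string(float_format=lambda v: f"{v: .6g}")

    def to_json_dict(self) -> dict:
        return {
            "intercept": self.intercept,
            "coefficients": self.coefficients.to_dict(),
            "std_errors": self.bse.to_dict(),
            "converged": self.converged,
            "n_iter": self.n_iter,
            "log_likelihood": self.llf,
        }


@dataclass
class ScoreDistribution:
    """Binned counts and density estimates of scores per prognosis group."""

    histogram: pd.DataFrame  # bin_left, bin_right, count_good, count_poor
    density: pd.DataFrame  # score, density_good, density_poor
    group_means: tuple[float, float]  # (good, poor)


def score_distribution_summary(
    scores: PropensityScores, n_bins: int = 20, n_grid: int = 201
) -> ScoreDistribution:
    """Summarize per-group score distributions for histogram/density plots.

    Bins partition [0, 1] half-open (last bin closed), so per-group counts
    sum to the group sizes. Densities are Gaussian KDEs on a [0, 1] grid; a
    group whose scores are (numerically) constant gets a degenerate
    all-zero density rather than an error.
    """
    from scipy.stats import gaussian_kde

    good, poor = scores.by_group()
    edges = np.linspace(0.0, 1.0, n_bins + 1)
    h_good, _ = np.histogram(good, bins=edges)
    h_poor, _ = np.histogram(poor, bins=edges)
    hist = pd.DataFrame(
        {
            "bin_left": edges[:-1],
            "bin_right": edges[1:],
            "count_good": h_good,
            "count_poor": h_poor,
        }
    )
    grid = np.linspace(0.0, 1.0, n_grid)
    dens = {}
    for label, sample in (("good", good), ("poor", poor)):
        if len(sample) > 1 and float(np.std(sample)) > 1e-12:
            dens[label] = gaussian_kde(sample.to_numpy())(grid)
        else:
            dens[label] = np.zeros_like(grid)
    density = pd.DataFrame(
        {"score": grid, "density_good": dens["good"], "density_poor": dens["poor"]}
    )
    return ScoreDistribution(
        histogram=hist,
        density=density,
        group_means=(float(good.mean()), float(poor.mean())),
    )
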