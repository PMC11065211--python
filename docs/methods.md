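# Methods

## Model and procedure

The pipeline treats prognosis-group membership as a binary "treatment"
whose assignment must be modeled before marker comparisons are meaningful.
The propensity score is the conditional probability of poor prognosis
given clinicopathological covariates, `e(x) = Pr(Z = 1 | x)`, estimated by
a maximum-likelihood binomial logit (statsmodels GLM, IRLS, convergence
tolerance 1e-8, iteration cap 100). No regularization is applied: if the
data separate, the MLE does not exist and the fit raises a `SeparationError`
naming the offending covariate rather than returning silently shrunken
coefficients. Rank-deficient designs likewise raise with the collinear
columns named. Binary covariates are coded 0/1 and ordinal covariates
(TNM stage, tumor differentiation) enter as their integer grade; scores
are the logistic transform of the fitted linear predictor.

Matching is greedy nearest-neighbor without replacement under a caliper.
The caliper is an **absolute difference on the probability scale**
(default 0.2) — deliberately the literal protocol rule, not the common
0.2 × SD-of-logit convention; the two disagree and the choice is exposed
in `MatchConfig`. A difference exactly equal to the caliper is rejected
(strict `<`); the boundary case is not otherwise defined and strictness
keeps the accepted-set definition open. Focal cases (the smaller group)
are processed in ascending score order. Distance ties prefer the
lower-scoring candidate, then the lexicographically smaller subject id,
making every run fully deterministic. For k:1 matching a focal case must
find all k partners within the caliper or it is excluded and its
provisionally taken partners return to the pool — this keeps the extracted
groups exactly k:1.

### Why ascending order

Scores in cohorts like these are right-skewed: most cases sit at low
propensity, few at high. Processing descending makes the matched partner
systematically *lower*-scoring than its focal case (there is usually
nothing above), so covariate differences survive matching. We verified the
quantitative version of this on the tuned scenario: the mean signed
(partner − focal) score difference under a descending sort is negative in
essentially every replicate, and its magnitude exceeds the ascending
sort's in 98/100 seeds. Note the benefit is *bias*, not yield: descending
processing actually accepts as many or more pairs (it serves the
hard high-score cases while scarce high-score partners are still free);
ascending is preferred because the pairs it accepts are closer, which is
what balance requires.

## Balance and marker statistics

Continuous and ordinal covariates are compared by a pooled-variance
Student t-test (Welch exposed as an option; with real data the choice is
consequential and should be reported). Categorical covariates use the
chi-squared test — with Yates continuity correction for 2×2 tables, which
is the variant that reproduces independently published contingency
p-values from printed counts (see `psmatch.datasets`), and uncorrected
Pearson for 2×K. Expected cell counts below 5 are flagged, not fatal.
Balance rows use p < 0.05 per covariate with no multiplicity correction,
matching how such cohort tables are conventionally read. "Unknown"
categorical levels are merged into the negative/reference level at ingest.

Score-panel markers are tested marker-wise (t-test for bounded scores,
Yates chi-squared for binary calls) at raw p < 0.05 without correction —
the convention for small curated panels. The count layer controls FDR by
Benjamini–Hochberg at 0.05 instead, as appropriate for genome-wide tests.

### The count-layer test is a transparent substitute

The canonical pipelines for such data (TMM normalization, voom precision
weights, empirical-Bayes moderated t) pool variance information across
genes. Here each gene is tested independently: CPM normalization,
expression filtering, log2(CPM + 0.5), Welch t. The structure (normalize →
filter → test → adjust) is the same; per-gene counts of significant genes
will *not* numerically match a moderated pipeline, especially at small n,
and result metadata records the substitution. The filter rule "CPM ≥
threshold in at least min(group sizes) subjects" follows filterByExpr-like
logic; a mean-CPM rule is the config alternative, and the rule used is
logged because the phrase "CPM < 15 filtered out" underdetermines it.
The filter is recomputed on the matched sub-cohort, so pre- and
post-matching gene universes differ; set comparisons use their
intersection.

## Synthetic cohorts

The generator emulates a two-arm prognosis cohort: covariates drawn
marginally (Gaussian / Bernoulli / categorical-ordinal), an outcome drawn
from `Bernoulli(logistic(b₀ + Σ bᵢxᵢ))` — so confounding is structural,
not accidental — and marker layers on top:

* score panel: `baseline + effect·Z + Σ loading·x̃ + N(0, σ)`, clipped to
  the declared range (0–300 weighted scores, 0–100 percent-positive) or
  thresholded to a binary call; `x̃` is the covariate standardized by its
  *specified* marginal moments, so a loading is "signal units per SD";
* counts: negative-binomial with `log2 μ = log2(baseline·ℓ) + effect·Z +
  Σ loading·x̃`, i.e. effects are log2 fold changes; library factors `ℓ`
  are log-normal (σ = 0.2, mean 1).

All draws flow from one integer seed through per-layer `SeedSequence`
sub-streams; identical spec + seed is bit-identical.

The canonical `confounded_marker_scenario` (n = 400) uses age
(N(64, 12²), coefficient −0.071/yr — chosen so the poor group is ~8 years
younger, a typical prognosis-cohort gap), TNM stage (grades 1–4,
coefficient +0.8/grade), plus gender and lymphatic invasion as
non-generating covariates; the intercept puts poor prevalence near 25%,
yielding ~85 matched pairs. Markers (0–300 scale, noise SD 30): a true
marker (effect +25), a spurious marker (loading 30 per stage-SD, no
effect), and a null marker. With these settings, over 100 seeds: both
confounders significant pre-matching in 100% of replicates and
non-significant post-matching in 100%; the spurious marker significant
pre in ~99% and post in ≤1%; the true marker retained post in 100%.

What the generator does **not** emulate: survival times and censoring
(the outcome dichotomy is generated directly), covariate–covariate
correlation (covariates are independent given the spec), marker–marker
correlation beyond shared confounders, batch effects, and missing data.
Passing tests therefore demonstrate that the machinery removes the
confounding it models, not that any particular real cohort is free of
residual or unmeasured confounding — the method's standard caveat.

## Numerical and scale choices

* Matching runs in O(n log n + m·n) with a sorted candidate pool; cohorts
  of a few thousand subjects match in milliseconds.
* Monte-Carlo checks use 100 replicates at n = 400 (pipeline properties)
  and 20 replicates × 1000 genes at 28 vs 28 (null calibration of the
  count test, which lands at 5.0 ± 0.3%); these sizes give stable rates
  while keeping the full suite under ten seconds.
* Propensity scores are validated to lie strictly in (0, 1); degenerate
  fitted probabilities trigger the separation error path.
* Empty match results produce an empty cohort with intact schema, so
  downstream code can handle pathological calipers gracefully.

## Known limitations

* Greedy matching is order-dependent by design (that is the protocol);
  optimal/network-flow matching, matching with replacement and weighting
  schemes are out of scope.
* The logit-based score model is the only propensity model offered — no
  covariate selection, no machine-learned scores.
* Standardized-mean-difference balance summaries are not part of the
  balance table (tests and p-values are what the table reports), though
  the ingredients are trivially available from the cohort object.
* Count-layer results are calibrated for the simple per-gene test; users
  wanting moderated statistics should export the matched cohort and run
  their preferred pipeline on it.
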