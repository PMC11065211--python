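"""Greedy caliper matcher: hand traces, invariants, oracle equivalence."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from oracles import trace_match

from conftest import make_cohort, scores_frame
from psmatch.matching import MatchConfig, MatchResult, extract_matched_cohort, greedy_match
from psmatch.propensity import PropensityModel, PropensityScores


def run_both(focal, candidates, caliper=0.2, ratio=1, order="ascending"):
    ps = scores_frame(focal, candidates)
    result = greedy_match(ps, MatchConfig(caliper=caliper, ratio=ratio), order=order)
    score_by_id = ps.scores.to_dict()
    group_by_id = ps.groups.to_dict()
    oracle = trace_match(score_by_id, group_by_id, caliper=caliper, ratio=ratio,
                         order=order)
    return result, oracle


def test_single_nearest_within_caliper():
    result = greedy_match(scores_frame([0.30], [0.25, 0.60]))
    assert result.pairs == [("P0", ("G0",))]
    assert result.pair_diffs == [(pytest.approx(0.05),)]
    assert result.unused == ["G1"]


def test_caliper_violation_excludes_focal_keeps_candidate():
    result = greedy_match(scores_frame([0.90], [0.10]))
    assert result.pairs == []
    assert result.excluded == ["P0"]
    assert result.unused == ["G0"]


def test_hand_trace_ascending_two_pairs():
    # ascending processes 0.10 first: (0.10, 0.12) then (0.50, 0.48); 0.90 unused
    result = greedy_match(scores_frame([0.10, 0.50], [0.12, 0.48, 0.90]))
    got = {(f, ms[0]) for f, ms in result.pairs}
    assert got == {("P0", "G0"), ("P1", "G1")}
    assert result.unused == ["G2"]
    assert result.pair_diffs == [(pytest.approx(0.02),), (pytest.approx(0.02),)]


def test_ratio_two_takes_two_nearest_within_caliper():
    result = greedy_match(scores_frame([0.50], [0.45, 0.52, 0.90]),
                          MatchConfig(ratio=2))
    assert result.pairs == [("P0", ("G1", "G0"))]  # nearest first: 0.52 then 0.45
    assert result.unused == ["G2"]


def test_ratio_two_insufficient_candidates_restores_pool():
    # only one candidate within the caliper: focal excluded, pool intact
    result = greedy_match(scores_frame([0.50], [0.48, 0.90]), MatchConfig(ratio=2))
    assert result.pairs == []
    assert result.excluded == ["P0"]
    assert sorted(result.unused) == ["G0", "G1"]


def test_caliper_boundary_is_strict():
    # 0.75 - 0.5 and the caliper 0.25 are exact binary fractions, so the
    # difference equals the caliper exactly and must be rejected
    result = greedy_match(scores_frame([0.50], [0.75]), MatchConfig(caliper=0.25))
    assert result.pairs == [] and result.excluded == ["P0"]
    result = greedy_match(scores_frame([0.50], [0.75]), MatchConfig(caliper=0.2500001))
    assert result.n_pairs == 1


def test_tie_prefers_lower_score_then_smaller_id():
    # candidates exactly equidistant (0.25 each side) — lower score wins
    result = greedy_match(scores_frame([0.50], [0.75, 0.25]), MatchConfig(caliper=0.3))
    assert result.pairs[0][1][0] == "G1"
    # equal scores: lexicographically smaller id wins
    result = greedy_match(scores_frame([0.50], [0.45, 0.45]))
    assert result.pairs[0][1][0] == "G0"


def test_focal_role_goes_to_smaller_group():
    ps = scores_frame([0.3, 0.4, 0.5], [0.3, 0.4])  # poor larger than good
    result = greedy_match(ps)
    assert result.focal_group == 0
    ps_eq = scores_frame([0.3, 0.4], [0.3, 0.4])
    assert greedy_match(ps_eq, MatchConfig(focal_group=1)).focal_group == 1
    assert greedy_match(ps_eq, MatchConfig(focal_group=0)).focal_group == 0


def test_pool_exhaustion_excludes_remaining_focal():
    result = greedy_match(scores_frame([0.1, 0.1], [0.4, 0.4, 0.4]),
                          MatchConfig(caliper=0.5, ratio=2))
    assert result.n_pairs == 1
    assert len(result.excluded) == 1  # pool too small for a second pair set


@pytest.mark.parametrize("ratio", [1, 2])
@pytest.mark.parametrize("caliper", [0.05, 0.2, 0.5])
def test_oracle_equivalence_small_random_instances(ratio, caliper):
    # literal flow-chart trace agrees on every instance with <= 8 per group
    rng = np.random.default_rng(2024)
    for _ in range(120):
        n_f = rng.integers(1, 9)
        n_c = rng.integers(1, 9)
        focal = np.round(rng.uniform(0.01, 0.99, n_f), 3)
        cand = np.round(rng.uniform(0.01, 0.99, n_c), 3)
        if n_c <= n_f:  # keep poor the (weakly) smaller group for this check
            continue
        result, (opairs, oexcl, ounused) = run_both(focal, cand, caliper, ratio)
        assert result.pairs == opairs
        assert result.excluded == oexcl
        assert sorted(result.unused) == ounused


@settings(max_examples=150, deadline=None, derandomize=True)
@given(
    focal=st.lists(st.integers(1, 999), min_size=1, max_size=8),
    cand=st.lists(st.integers(1, 999), min_size=1, max_size=8),
    caliper=st.sampled_from([0.05, 0.2, 0.35]),
    ratio=st.integers(1, 3),
)
def test_matching_invariants_property(focal, cand, caliper, ratio):
    focal = [v / 1000 for v in focal]
    cand = [v / 1000 for v in cand]
    ps = scores_frame(focal, cand)
    result = greedy_match(ps, MatchConfig(caliper=caliper, ratio=ratio))
    matched_cands = result.matched_candidate_ids
    # no duplicates among matched larger-group ids
    assert len(matched_cands) == len(set(matched_cands))
    # every recorded difference respects the (strict) caliper
    assert all(d < caliper for ds in result.pair_diffs for d in ds)
    # exact k:1 structure
    assert len(matched_cands) == result.n_pairs * ratio
    # every focal case accounted for exactly once
    n_focal = len(focal) if result.focal_group == 1 else len(cand)
    assert result.n_pairs + len(result.excluded) == n_focal
    # oracle equivalence on the same instance
    opairs, oexcl, ounused = trace_match(
        ps.scores.to_dict(), ps.groups.to_dict(), caliper=caliper, ratio=ratio
    )
    assert result.pairs == opairs and result.excluded == oexcl


def test_extract_matched_cohort_sizes_and_layers(scenario):
    cohort, _ = scenario
    res = PropensityModel.from_cohort(cohort).fit()
    scores = res.score_cohort(cohort)
    for ratio in (1, 2):
        result = greedy_match(scores, MatchConfig(ratio=ratio))
        matched = extract_matched_cohort(cohort, result)
        n_good, n_poor = matched.group_sizes
        assert n_poor == result.n_pairs
        assert n_good == ratio * result.n_pairs  # k:1 structure
        assert matched.layer("score_panel").shape[1] == matched.n_subjects


def test_extract_empty_result_keeps_schema(scenario):
    cohort, _ = scenario
    empty = MatchResult(pairs=[], pair_diffs=[], excluded=["x"], unused=[],
                        focal_group=1)
    # excluded id need not exist in the cohort; only matched ids are taken
    sub = extract_matched_cohort(cohort, empty)
    assert sub.n_subjects == 0
    assert list(sub.covariates.columns) == list(cohort.covariates.columns)
    assert sorted(sub.layers) == sorted(cohort.layers)


def test_ascending_order_reduces_pairing_bias(scenario):
    # the protocol's rationale: with a descending sort the matched partner
    # systematically sits below the focal score; ascending keeps the signed
    # score difference near zero
    cohort, _ = scenario
    scores = PropensityModel.from_cohort(cohort).fit().score_cohort(cohort)
    bias = {}
    for order in ("ascending", "descending"):
        result = greedy_match(scores, order=order)
        diffs = [scores.scores[m] - scores.scores[f]
                 for f, ms in result.pairs for m in ms]
        bias[order] = float(np.mean(diffs))
    assert abs(bias["ascending"]) < abs(bias["descending"])
    assert bias["descending"] < 0  # partners consistently lower-scored


def test_duplicate_matched_ids_rejected_by_result_invariant():
    with pytest.raises(ValueError, match="duplicate"):
        MatchResult(pairs=[("a", ("c",)), ("b", ("c",))],
                    pair_diffs=[(0.01,), (0.01,)], excluded=[], unused=[],
                    focal_group=1)
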