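"""Greedy caliper matching on propensity scores, without replacement.

The stepwise protocol: cases of the smaller prognosis group are sorted
ascending by propensity score and each is paired, in turn, with the
not-yet-used case of the larger group whose score is most similar. A pair
is accepted only if the absolute score difference is below the caliper
(default 0.2 on the probability scale — the literal rule used here, not the
more common 0.2 x SD-of-logit convention); otherwise the focal case is
excluded and the candidate stays available for later rounds. Accepted
counterparts leave the pool, so the two extracted groups contain no
duplicates. The ascending order exists because low-score cases are easier
to match; taking them first avoids burning close candidates on hard cases.

``ratio=k`` generalizes to k-to-1 matching: each focal case takes its k
nearest unused candidates, each individually within the caliper; if fewer
than k qualify the focal case is excluded entirely (provisional candidates
return to the pool), keeping the extracted groups exactly k:1.

Determinism: score-distance ties prefer the lower-scoring candidate, then
the lexicographically smaller subject id.
"""

from __future__ import annotations

import bisect
from dataclasses import dataclass, field

import pandas as pd

from .cohort import Cohort, CohortError
from .propensity import PropensityScores

__all__ = ["MatchConfig", "MatchResult", "greedy_match", "extract_matched_cohort"]


@dataclass(frozen=True)
class MatchConfig:
    """Matching parameters.

    caliper
        Maximum absolute propensity-score difference for an acceptable
        pair, on the probability scale. A difference exactly equal to the
        caliper is rejected (strict ``<``).
    ratio
        Candidates matched per focal case (1 for pairs, 2 for 2-to-1).
    focal_group
        Which group supplies the focal cases when the two groups have equal
        size; the smaller group is focal whenever sizes differ.
    """

    caliper: float = 0.2
    ratio: int = 1
    focal_group: int = 1  # poor prognosis by default

    def __post_init__(self) -> None:
        if not self.caliper > 0:
            raise ValueError("caliper must be > 0")
        if self.ratio < 1:
            raise ValueError("ratio must be >= 1")
        if self.focal_group not in (0, 1):
            raise ValueError("focal_group must be 0 or 1")


@dataclass
class MatchResult:
    """Outcome of one greedy matching run."""

    pairs: list[tuple[str, tuple[str, ...]]]  # (focal id, matched candidate ids)
    pair_diffs: list[tuple[float, ...]]  # |score difference| per matched candidate
    excluded: list[str]  # focal ids that failed the caliper
    unused: list[str]  # larger-group ids never matched
    focal_group: int  # group label (0/1) that supplied focal cases
    config: MatchConfig = field(default=MatchConfig())

    def __post_init__(self) -> None:
        matched = [m for _, ms in self.pairs for m in ms]
        if len(matched) != len(set(matched)):
            raise ValueError("duplicate matched candidate ids")
        focal = [f for f, _ in self.pairs] + list(self.excluded)
        if len(focal) != len(set(focal)):
            raise ValueError("focal id recorded more than once")
        for diffs in self.pair_diffs:
            if any(d >= self.config.caliper for d in diffs):
                raise ValueError("recorded pair difference violates the caliper")

    @property
    def n_pairs(self) -> int:
        return len(self.pairs)

    @property
    def matched_focal_ids(self) -> list[str]:
        return [f for f, _ in self.pairs]

    @property
    def matched_candidate_ids(self) -> list[str]:
        return [m for _, ms in self.pairs for m in ms]

    @property
    def matched_ids(self) -> list[str]:
        """All matched subjects, focal cases first."""
        return self.matched_focal_ids + self.matched_candidate_ids

    def to_frame(self) -> pd.DataFrame:
        """Tabular export: one row per focal case, matched or excluded."""
        rows = [
            {
                "focal_id": f,
                "matched_ids": ";".join(ms),
                "abs_score_diff": ";".join(f"{d:.6g}" for d in ds),
                "status": "matched",
            }
            for (f, ms), ds in zip(self.pairs, self.pair_diffs)
        ]
        rows += [
            {"focal_id": f, "matched_ids": "", "abs_score_diff": "", "status": "excluded"}
            for f in self.excluded
        ]
        return pd.DataFrame(rows, columns=["focal_id", "matched_ids", "abs_score_diff", "status"])


class _CandidatePool:
    """Sorted (score, id) pool supporting nearest-neighbor pop.

    Tie policy for equidistant candidates: lower score wins; equal scores
    fall back to the smaller id (the sort order within equal scores).
    """

    def __init__(self, scores: pd.Series):
        self._items = sorted(zip(scores.to_numpy(dtype=float), scores.index.astype(str)))

    def __len__(self) -> int:
        return len(self._items)

    def nearest(self, score: float) -> tuple[float, str, float]:
        """(candidate score, candidate id, |difference|) of the nearest entry."""
        items = self._items
        j = bisect.bisect_left(items, (score,))
        best = None
        if j > 0:  # nearest below: among equal scores, the smallest id
            s = items[j - 1][0]
            first = bisect.bisect_left(items, (s,))
            cid = items[first][1]
            best = (abs(score - s), s, cid)
        if j < len(items):
            s, cid = items[j]
            cand = (abs(score - s), s, cid)
            # on exact distance ties the lower score wins
            if best is None or cand < best:
                best = cand
        d, s, cid = best
        return s, cid, d

    def remove(self, cid: str, score: float) -> None:
        self._items.remove((score, cid))

    def add(self, cid: str, score: float) -> None:
        bisect.insort(self._items, (score, cid))

    def ids(self) -> list[str]:
        return [cid for _, cid in self._items]


def greedy_match(
    scores: PropensityScores,
    config: MatchConfig | None = None,
    order: str = "ascending",
) -> MatchResult:
    """Run the ascending-sort greedy caliper match.

    The focal role goes to the smaller group (ties broken by
    ``config.focal_group``); its cases are processed from the smallest
    propensity score to the largest, with id as a deterministic tiebreak.
    ``order="descending"`` reverses the processing order — a diagnostic for
    demonstrating why ascending is the better protocol, not a recommended
    setting.
    """
    if order not in ("ascending", "descending"):
        raise ValueError("order must be 'ascending' or 'descending'")
    config = config or MatchConfig()
    good, poor = scores.by_group()
    if len(good) == 0 or len(poor) == 0:
        raise ValueError("both prognosis groups must be nonempty")
    sizes = {0: len(good), 1: len(poor)}
    if sizes[0] == sizes[1]:
        focal_group = config.focal_group
    else:
        focal_group = min(sizes, key=lambda g: sizes[g])
    focal_scores = poor if focal_group == 1 else good
    cand_scores = good if focal_group == 1 else poor

    pool = _CandidatePool(cand_scores)
    focal_order = sorted(
        zip(focal_scores.to_numpy(dtype=float), focal_scores.index.astype(str)),
        reverse=(order == "descending"),
    )

    pairs: list[tuple[str, tuple[str, ...]]] = []
    pair_diffs: list[tuple[float, ...]] = []
    excluded: list[str] = []
    for fscore, fid in focal_order:
        if len(pool) < config.ratio:
            excluded.append(fid)  # pool exhausted: remaining focal cases excluded
            continue
        taken: list[tuple[str, float, float]] = []  # (id, score, diff)
        ok = True
        for _ in range(config.ratio):
            cscore, cid, diff = pool.nearest(fscore)
            if diff < config.caliper:
                pool.remove(cid, cscore)
                taken.append((cid, cscore, diff))
            else:
                ok = False
                break
        if ok:
            pairs.append((fid, tuple(t[0] for t in taken)))
            pair_diffs.append(tuple(t[2] for t in taken))
        else:
            # caliper failure: focal case excluded, provisional candidates
            # restored for later rounds
            for cid, cscore, _ in taken:
                pool.add(cid, cscore)
            excluded.append(fid)

    return MatchResult(
        pairs=pairs,
        pair_diffs=pair_diffs,
        excluded=excluded,
        unused=pool.ids(),
        focal_group=focal_group,
        config=config,
    )


def extract_matched_cohort(cohort: Cohort, result: MatchResult) -> Cohort:
    """Sub-cohort of exactly the matched subjects, marker layers included.

    An empty match yields an empty cohort with the schema intact.
    """
    ids = [i for i in result.matched_ids]
    missing = [i for i in ids if i not in cohort.subject_ids]
    if missing:
        raise CohortError(f"match result references unknown subjects: {missing[:5]}")
    # preserve the cohort's own subject order
    keep = set(ids)
    ordered = [i for i in cohort.subject_ids if i in keep]
    return cohort.subset(ordered)
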