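import numpy as np
import pandas as pd
import pytest

from psmatch.cohort import Cohort
from psmatch.simulate import confounded_marker_scenario


@pytest.fixture(scope="session")
def scenario():
    """One canonical confounded cohort plus marker truth labels."""
    return confounded_marker_scenario(seed=7)


def make_cohort(n_good=30, n_poor=10, seed=0, extra_cov=False):
    """Small hand-rolled cohort for unit tests (independent of simulate)."""
    rng = np.random.default_rng(seed)
    n = n_good + n_poor
    ids = pd.Index([f"s{i:03d}" for i in range(n)], name="subject_id")
    covs = pd.DataFrame(
        {
            "age": rng.normal(60, 10, n),
            "stage": rng.integers(1, 5, n),
        },
        index=ids,
    )
    kinds = {"age": "continuous", "stage": "ordinal"}
    if extra_cov:
        covs["invasion"] = rng.integers(0, 2, n)
        kinds["invasion"] = "binary"
    outcome = pd.Series([0] * n_good + [1] * n_poor, index=ids)
    return Cohort(covariates=covs, outcome=outcome, kinds=kinds)


def scores_frame(focal, candidates):
    """PropensityScores built from two explicit score lists."""
    from psmatch.propensity import PropensityScores

    ids = [f"P{i}" for i in range(len(focal))] + [f"G{i}" for i in range(len(candidates))]
    s = pd.Series(list(focal) + list(candidates), index=ids, dtype=float)
    g = pd.Series([1] * len(focal) + [0] * len(candidates), index=ids)
    return PropensityScores(scores=s, groups=g)
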