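import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

import jointharvest as jh

settings.register_profile("default", derandomize=True, deadline=None, max_examples=50)
settings.load_profile("default")


@pytest.fixture(scope="session")
def turkey_data():
    return jh.make_case_study_fixture("turkey", np.random.default_rng(42))


@pytest.fixture(scope="session")
def deer_data():
    return jh.make_case_study_fixture("deer", np.random.default_rng(42))


@pytest.fixture
def tiny_known_fate():
    """Two-interval series obeying the at-risk bookkeeping identity."""
    return jh.KnownFateSeries(
        pd.DataFrame(
            {
                "stratum": ["all", "all"],
                "year": [1, 1],
                "month": [1, 2],
                "n": [10, 7],
                "d": [2, 1],
                "c": [1, 0],
                "e": [10, 0],
            }
        )
    )


def make_recovery_data(released, counts_by_cohort):
    """Build RecoveryData for one-cohort-per-year releases.

    ``counts_by_cohort[i]`` holds recoveries of the year-(i+1) cohort in years
    i+1, i+2, ...
    """
    releases = pd.DataFrame(
        {
            "year": range(1, len(released) + 1),
            "entry_month": 1,
            "age": "all",
            "unit": "all",
            "tag_type": "tag",
            "released": released,
        }
    )
    rows = []
    for i, counts in enumerate(counts_by_cohort):
        for offset, count in enumerate(counts):
            if count:
                rows.append((i + 1, 1, "all", "all", "tag", i + 1 + offset, count))
    recoveries = pd.DataFrame(
        rows,
        columns=[
            "year_released",
            "entry_month",
            "age",
            "unit",
            "tag_type",
            "year_recovered",
            "count",
        ],
    )
    return jh.RecoveryData(releases=releases, recoveries=recoveries)
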