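import numpy as np
import pandas as pd
import pytest

from pansimc.instruments import ResponseMatrix, builtin_specs, score_all
from pansimc.synthetic import CohortSpec, generate_cohort


@pytest.fixture(scope="session")
def specs():
    return builtin_specs()


@pytest.fixture(scope="session")
def default_cohort():
    """A study-sized synthetic cohort (n=413, reported correlation targets)."""
    return generate_cohort(CohortSpec(seed=1))


@pytest.fixture(scope="session")
def default_scores(default_cohort):
    return score_all(default_cohort)


def make_responses(spec, fill):
    """Single-respondent ResponseMatrix with every item of `spec` set to
    `fill` ('min', 'max', or an int)."""
    row = {}
    for item in spec.items:
        if fill == "min":
            v = item.min_response
        elif fill == "max":
            v = item.max_response
        else:
            v = fill
        row[spec.column(item.item_id)] = [v]
    return ResponseMatrix(pd.DataFrame(row))


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
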