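import numpy as np
import pytest

import valueshift as vs
from valueshift.core import HealthState, TTOObservation, RespondentRecord, DemographicCell
from valueshift.io import ValuationDataset
from valueshift.model import CompiledData


def make_respondent(rid, sex, age_group, codes, values):
    obs = [TTOObservation(rid, HealthState(c), v) for c, v in zip(codes, values)]
    return RespondentRecord(rid, DemographicCell(sex, age_group), obs)


@pytest.fixture(scope="session")
def small_dataset():
    """A tiny deterministic clean dataset spanning all 8 cells."""
    rng = np.random.default_rng(42)
    truth = vs.default_truth("UK", n_respondents=40, contaminate=False)
    return vs.simulate_study(truth, rng=rng)


@pytest.fixture(scope="session")
def small_compiled(small_dataset):
    return CompiledData.from_dataset(small_dataset)


@pytest.fixture(scope="session")
def uk_truth():
    return vs.default_truth("UK", n_respondents=300, contaminate=False)
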