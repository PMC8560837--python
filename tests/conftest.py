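import numpy as np
import pytest

from isleprs import prs_engine as prs
from isleprs import synthetic_cohorts as syn


@pytest.fixture(scope="session")
def scenario_1x():
    """One full-size default scenario shared by the tests that only read it."""
    return syn.default_scenario(11)


@pytest.fixture(scope="session")
def scenario_scores(scenario_1x):
    """Pooled z-scores per (cohort, subset) for the shared scenario."""
    out = {}
    for subset in ("full", "no_hla", "hla_only"):
        raw = [prs.score(dm, scenario_1x.panel, subset) for dm, _ in scenario_1x.cohorts.values()]
        for sv in prs.pooled_zscore(raw):
            out[(sv.cohort, sv.subset_name)] = sv
    return out


@pytest.fixture
def rng():
    return np.random.default_rng(20240901)
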