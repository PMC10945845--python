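import numpy as np
import pytest

from vigilread import SimConfig, simulate_cohort
from vigilread.io import attach_women
from vigilread.sessions import BreakDefinition, apply_exclusions, included, segment_sessions


@pytest.fixture(scope="session")
def default_cohort():
    """A mid-sized simulated cohort shared across read-only tests."""
    config = SimConfig(n_women=50_000, seed=101)
    women, events = simulate_cohort(config)
    return config, women, events


@pytest.fixture(scope="session")
def analysis_records(default_cohort):
    """First-reader analysis records under the 20-min break definition."""
    _, women, events = default_cohort
    merged = attach_women(events, women)
    positioned = segment_sessions(merged, BreakDefinition(20.0))
    records = included(apply_exclusions(positioned))
    return records[records["position"] <= 200]


@pytest.fixture()
def rng():
    return np.random.default_rng(7)
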