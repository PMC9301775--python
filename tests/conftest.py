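import sys
from pathlib import Path

import pytest

sys.path.insert(0, str(Path(__file__).parent))  # make oracles importable

from prosocial import (
    EffortParams,
    HarmParams,
    generate_effort_trialset,
    generate_harm_trialset,
    simulate_effort_choices,
    simulate_harm_choices,
)


@pytest.fixture(scope="session")
def harm_trials():
    return generate_harm_trialset(seed=11)


@pytest.fixture(scope="session")
def effort_trials():
    return generate_effort_trialset()


@pytest.fixture(scope="session")
def compliant_harm_records(harm_trials):
    return simulate_harm_choices(HarmParams(0.3, 0.6, 5.0, 5.0), harm_trials, seed=21)


@pytest.fixture(scope="session")
def effort_records(effort_trials):
    return simulate_effort_choices(
        EffortParams(0.02, 0.10, 2.0), effort_trials, seed=22, miss_rate=0.05
    )
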