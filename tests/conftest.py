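import pytest

from tsakit import DesignSpec, TrialRecord
from tsakit.datasets import MIQUIT_ANALYSED, miquit_design, miquit_trials, scenario_trial


@pytest.fixture
def miquit():
    return miquit_trials()


@pytest.fixture
def design() -> DesignSpec:
    return miquit_design()


@pytest.fixture
def analysed() -> int:
    return MIQUIT_ANALYSED


@pytest.fixture
def scenario_c() -> TrialRecord:
    return scenario_trial("C")


@pytest.fixture
def scenario_d() -> TrialRecord:
    return scenario_trial("D")
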