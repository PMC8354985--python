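import pytest

from casemix.model import build_worked_example
from casemix.synthetic import generate_instance
from casemix.traditional import AllocationRule


@pytest.fixture()
def worked():
    return build_worked_example()


@pytest.fixture()
def rule():
    # $300K labor budget spread over 1500 effective OR-hours
    return AllocationRule(labor_rate=200.0, basis_resource="operating_room",
                          rate_time_unit="hour")


@pytest.fixture(scope="session")
def synth_instance():
    """One medium synthetic network shared by read-only tests."""
    return generate_instance(seed=11)
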