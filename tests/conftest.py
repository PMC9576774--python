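import pytest

from ishipment import load_fixture
from ishipment.demand import DemandSchedule, PatientArrival


@pytest.fixture(scope="session")
def tiny2():
    return load_fixture("tiny2")


@pytest.fixture(scope="session")
def paper6():
    return load_fixture("paper6")


@pytest.fixture
def two_patients():
    """Two patients checking in at the two tiny2 sites on days 2 and 3."""
    return DemandSchedule((PatientArrival("p1", "s1", 2),
                           PatientArrival("p2", "s2", 3)))


def make_demand(*arrivals):
    return DemandSchedule(tuple(PatientArrival(p, c, d)
                                for p, c, d in arrivals))
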