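import numpy as np
import pytest

from sertpet.synth import ReferenceInput, simulate_reference_tac
from sertpet.tac import DASB_FRAMING, TimeActivityCurve, make_frame_schedule


@pytest.fixture(scope="session")
def schedule():
    return make_frame_schedule(DASB_FRAMING)


@pytest.fixture(scope="session")
def ref_input():
    return ReferenceInput()


@pytest.fixture(scope="session")
def ref_tac(schedule, ref_input):
    return simulate_reference_tac(schedule, ref_input)


@pytest.fixture(scope="session")
def ref_measured(schedule, ref_tac):
    """Reference TAC as a fit would see it: frame values only, no fine curve."""
    return TimeActivityCurve(schedule, ref_tac.values, "cerebellum")


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
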