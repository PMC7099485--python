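import pytest

from wcentrain.model import example_params
from wcentrain.search import CandidateSet, check_conditions
from wcentrain.model import EXAMPLE_SET


@pytest.fixture(scope="session")
def example_q0():
    return example_params(0.0)


@pytest.fixture(scope="session")
def example_q1():
    return example_params(1.0)


@pytest.fixture(scope="session")
def example_candidate():
    """The reference parameter set with measured screening diagnostics."""
    cand = CandidateSet(**EXAMPLE_SET)
    return check_conditions(cand)
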