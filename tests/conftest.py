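import numpy as np
import pytest

from nof1bayes import ConditionLayout, parse_hypothesis
from nof1bayes.datasets import table1_hypotheses, table1_layout, table1_persons


@pytest.fixture(scope="session")
def layout4():
    return table1_layout()


@pytest.fixture(scope="session")
def ordering4(layout4):
    return parse_hypothesis("c1 > c2 > c3 > c4", layout4, label="H1")


@pytest.fixture(scope="session")
def averages4(layout4):
    return parse_hypothesis("(c1 + c2)/2 > (c3 + c4)/2", layout4, label="H2")


@pytest.fixture(scope="session")
def hset4():
    return table1_hypotheses()


@pytest.fixture(scope="session")
def persons4():
    return table1_persons()


@pytest.fixture(scope="session")
def layout8():
    return ConditionLayout([f"c{i}" for i in range(1, 9)], replications=21)


@pytest.fixture(scope="session")
def ordering8(layout8):
    return parse_hypothesis(" > ".join(layout8.names), layout8, label="H1")
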