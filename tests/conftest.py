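import numpy as np
import pytest

from heartscore import load_benchmarks, load_instrument
from heartscore.instrument import ResponseRecord


@pytest.fixture(scope="session")
def instrument():
    return load_instrument()


@pytest.fixture(scope="session")
def benchmarks():
    return load_benchmarks()


def make_record(instrument, value=4, participant_id="P0001", visit="baseline", overrides=None):
    """A complete response record with every item set to `value` (on the
    recorded scale, i.e. reversed items are flipped so the oriented value
    is `value`), plus optional raw overrides."""
    resp = {}
    for item in instrument.items:
        v = value
        if item.polarity.value == "reversed" and v is not None:
            v = 7 - v
        resp[item.item_id] = v
    if overrides:
        resp.update(overrides)
    return ResponseRecord(participant_id=participant_id, visit=visit, responses=resp)


@pytest.fixture
def rng():
    return np.random.default_rng(20260930)
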