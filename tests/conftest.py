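import numpy as np
import pytest

import mibci
from mibci.evaluate import preprocess_recording
from mibci.preprocess import EpochSet, WindowSpec, rescale


@pytest.fixture(scope="session")
def short_protocol():
    """Desk-scale session: 12 s segments, 5 trials (2 s discards apply)."""
    return mibci.make_protocol(trials=5, segment_s=12.0)


@pytest.fixture(scope="session")
def default_recording(short_protocol):
    """One trial of default synthetic EEG at 500 Hz."""
    return mibci.simulate_recording(mibci.SimConfig(seed=11), short_protocol, 0, 0)


@pytest.fixture(scope="session")
def default_subject(short_protocol):
    """Five trials of one synthetic subject (for cross-validation)."""
    return mibci.simulate_subject(mibci.SimConfig(seed=11), short_protocol, 0)


@pytest.fixture(scope="session")
def conditioned_epochs(default_subject):
    """Windows (2 s, 50 % overlap) from all five conditioned recordings."""
    sets = [
        mibci.segment(preprocess_recording(r), WindowSpec(2.0, 0.5), 2.0)
        for r in default_subject
    ]
    return EpochSet.concatenate(sets)
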