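import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # for the oracles helper

from rootseg import cli, phantom


@pytest.fixture(scope="session")
def default_spec() -> phantom.PhantomSpec:
    return phantom.PhantomSpec(seed=1)


@pytest.fixture(scope="session")
def default_truth(default_spec) -> phantom.PhantomTruth:
    """One untreated phantom pair shared by the whole session."""
    return phantom.generate_hemijaw_pair(default_spec)


@pytest.fixture(scope="session")
def default_seg(default_truth):
    """Automated segmentation of the shared untreated phantom."""
    return cli.segment_pair(default_truth, marker_seed=5)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(20240917)
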