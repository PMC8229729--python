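import json
import os
import sys

import numpy as np
import pytest

sys.path.insert(0, os.path.dirname(__file__))  # for oracles.py

from kesvr import fit_kesvr
from kesvr.synthetic import make_worked_fixture

WORKED_DIR = os.path.join(os.path.dirname(__file__), "data", "worked")


@pytest.fixture(scope="session")
def worked():
    """The frozen ~60-cell, 3-regime fixture (expr, resp, truth, genes)."""
    return make_worked_fixture()


@pytest.fixture(scope="session")
def worked_model(worked):
    """kESVR fitted on the worked fixture (k_max=4, seed=844)."""
    expr, resp, truth, genes = worked
    return fit_kesvr(expr, resp, genes, k_max=4, seed=844)


@pytest.fixture(scope="session")
def worked_expected():
    with open(os.path.join(WORKED_DIR, "expected.json")) as fh:
        return json.load(fh)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
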