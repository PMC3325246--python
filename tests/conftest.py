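import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))

from rtnstab import DynamicsSpec, EnsembleSpec, WeightMatrix


@pytest.fixture
def rng():
    return np.random.default_rng(20120412)


@pytest.fixture
def step_pm1():
    return DynamicsSpec(map="pm1", norm="step")


@pytest.fixture
def step_01():
    return DynamicsSpec(map="zero_one", norm="step")


def identity_factory(ens: EnsembleSpec, rng, i=0) -> WeightMatrix:
    """Degenerate ensemble: every matrix is the identity (all states fixed)."""
    return WeightMatrix(entries=np.eye(ens.n_genes), scheme="binary_pm1")


def neg_identity_factory(ens: EnsembleSpec, rng, i=0) -> WeightMatrix:
    """Degenerate ensemble: minus identity (every +/-1 state 2-cycles)."""
    return WeightMatrix(entries=-np.eye(ens.n_genes), scheme="binary_pm1")
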