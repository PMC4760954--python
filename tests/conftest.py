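"""Shared fixtures: synthetic sessions at two scales.

``default_session`` is the package's reference study condition (60 units,
30 blocks, planted L_value = 110 ms / L_dir = 60 ms) and is expensive;
the full latency report on it is computed once per test session.
``tiny_session`` is for structural tests.
"""

from __future__ import annotations

import numpy as np
import pytest

import seqsel
from seqsel.pipeline import sequential_latency_report

DEFAULT_SEED = 11


@pytest.fixture(scope="session")
def tiny_session():
    return seqsel.make_session(n_blocks=2, n_units=8, seed=3)


@pytest.fixture(scope="session")
def default_session():
    return seqsel.make_session(n_blocks=30, n_units=60, seed=DEFAULT_SEED)


@pytest.fixture(scope="session")
def latency_report(default_session):
    return sequential_latency_report(default_session, seed=DEFAULT_SEED)


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
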