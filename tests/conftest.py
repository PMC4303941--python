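"""Shared fixtures: the default synthetic cohort and its trained map.

The full-scale fixture (2000 proteins, 40x40 map) is session-scoped — it
backs the acceptance checks and a few geometry tests — while unit tests
mostly build their own tiny inputs.
"""

from __future__ import annotations

import numpy as np
import pytest

from somportrait import cohort as cohort_mod
from somportrait import io as io_mod
from somportrait.som import SomParams, train_som

COHORT_SEED = 1
SOM_SEED = 0


@pytest.fixture(scope="session")
def default_cohort():
    matrices, gt = cohort_mod.generate_cohort(seed=COHORT_SEED)
    return matrices, gt


@pytest.fixture(scope="session")
def mean_matrix(default_cohort):
    matrices, _ = default_cohort
    return io_mod.build_mean_volunteer(matrices)


@pytest.fixture(scope="session")
def diff_matrix(mean_matrix):
    return io_mod.centralize(mean_matrix)


@pytest.fixture(scope="session")
def trained_model(diff_matrix):
    return train_som(diff_matrix, SomParams(seed=SOM_SEED))


@pytest.fixture()
def rng():
    return np.random.default_rng(42)
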