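"""Shared fixtures: small synthetic datasets generated at test time."""

from __future__ import annotations

import numpy as np
import pytest

from conjointfp import (
    SyntheticConfig,
    gen_complexes,
    gen_molecules,
    gen_targets,
)


@pytest.fixture(scope="session")
def small_config() -> SyntheticConfig:
    return SyntheticConfig(n_molecules=60, seed=7)


@pytest.fixture(scope="session")
def small_molecules(small_config):
    return gen_molecules(small_config)


@pytest.fixture(scope="session")
def small_supervised(small_config, small_molecules):
    """60 molecules with planted-signal targets plus the ground truth."""
    ds, info = gen_targets(small_molecules, small_config, return_info=True)
    return ds, info


@pytest.fixture(scope="session")
def toy_complexes():
    return gen_complexes(3, seed=11)


@pytest.fixture(scope="session")
def random_bit_data():
    """Random 0/1 design matrix with a sparse linear target, no chemistry."""
    rng = np.random.default_rng(42)
    X = rng.integers(0, 2, size=(300, 60)).astype(float)
    w = np.zeros(60)
    w[[3, 17, 41]] = [1.0, -1.5, 2.0]
    y = X @ w
    return X, y, w
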