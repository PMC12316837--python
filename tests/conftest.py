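"""Shared fixtures.

Heavy artifacts (the scaled-down end-to-end dataset and trained detector)
are session-scoped and built lazily, so unit-test runs that do not touch
them stay fast.
"""

from __future__ import annotations

import numpy as np
import pytest

from hotspotmon import make_preset, run_generate, run_train


@pytest.fixture(scope="session")
def fixture_cfg():
    return make_preset("fixture", seed=7)


@pytest.fixture(scope="session")
def fixture_dataset(fixture_cfg):
    return run_generate(fixture_cfg)


@pytest.fixture(scope="session")
def fixture_model(fixture_cfg, fixture_dataset):
    model, history = run_train(fixture_cfg, fixture_dataset)
    return model, history


@pytest.fixture(scope="session")
def desk_cfg():
    return make_preset("desk", seed=11)


@pytest.fixture(scope="session")
def desk_dataset(desk_cfg):
    return run_generate(desk_cfg)


@pytest.fixture(scope="session")
def desk_model(desk_cfg, desk_dataset):
    model, history = run_train(desk_cfg, desk_dataset)
    return model, history


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
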