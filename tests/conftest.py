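"""Shared fixtures: memoised synthetic datasets and prepared tables.

Several tests replicate generator truths over many seeds; memoising the
(pure, deterministic) generation keeps the suite fast without coupling
tests to each other.
"""

from __future__ import annotations

import functools
import warnings

import pytest

from coresat import ScenarioConfig, filter_low_count_taxa, generate_scenario, rarefy


@functools.lru_cache(maxsize=None)
def dataset(seed: int = 0):
    return generate_scenario(ScenarioConfig(seed=seed))


@functools.lru_cache(maxsize=None)
def prepared(seed: int = 0, depth: str = "surface"):
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return rarefy(filter_low_count_taxa(dataset(seed).community[depth]), seed=seed)


@pytest.fixture(scope="session")
def default_dataset():
    return dataset(0)


@pytest.fixture(scope="session")
def surface_table():
    return prepared(0, "surface")


@pytest.fixture(scope="session")
def bottom_table():
    return prepared(0, "bottom")
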