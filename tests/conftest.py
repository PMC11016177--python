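"""Shared fixtures: the default mock community (generated once per session)
and a small three-species community for fast pipeline-level tests."""

from __future__ import annotations

import time

import numpy as np
import pytest
from hypothesis import settings

from cobiontscan.pipeline import PipelineConfig, run_pipeline
from cobiontscan.synthetic_community import (CommunitySpec, SpeciesSpec,
                                             default_community_spec,
                                             simulate_community)

settings.register_profile("ci", deadline=None, derandomize=True,
                          max_examples=50)
settings.load_profile("ci")


def small_community_spec(rng_seed: int = 3) -> CommunitySpec:
    """A compact host + two cobionts community for fast end-to-end tests."""
    species = [
        SpeciesSpec("Parvus dominus", "Hospitidae", "Eukaryota",
                    60_000, 0.40, 101, 40.0, fragments=2),
        SpeciesSpec("Minimus unus", "Symbiontaceae", "Bacteria",
                    30_000, 0.50, 103, 10.0, fragments=1),
        SpeciesSpec("Minimus duo", "Commensalaceae", "Bacteria",
                    25_000, 0.55, 107, 5.0, fragments=1),
    ]
    return CommunitySpec(species, coverage_total=55.0, rng_seed=rng_seed)


@pytest.fixture(scope="session")
def default_bundle(tmp_path_factory):
    out = tmp_path_factory.mktemp("default_fixture")
    bundle = simulate_community(default_community_spec(), out)
    return bundle, out


@pytest.fixture(scope="session")
def default_run(default_bundle):
    """The full pipeline executed once on the default community."""
    bundle, out = default_bundle
    config = PipelineConfig.from_yaml(out / "config.yaml")
    t0 = time.monotonic()
    result = run_pipeline(config)
    elapsed = time.monotonic() - t0
    return bundle, config, result, elapsed


@pytest.fixture(scope="session")
def small_bundle(tmp_path_factory):
    out = tmp_path_factory.mktemp("small_fixture")
    bundle = simulate_community(small_community_spec(), out)
    return bundle, out


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
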