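"""Shared fixtures: the seeded default study (with and without planted errors),
its full pipeline results, and small hand-built objects."""

import numpy as np
import pytest
from hypothesis import settings

from crossalign.cli import run_all
from crossalign.core_io import GeneticMap, GenotypeTable
from crossalign.simulate import SimConfig, simulate_study

settings.register_profile("suite", derandomize=True, deadline=None, max_examples=50)
settings.load_profile("suite")

DEFAULT_SEED = 0


@pytest.fixture(scope="session")
def default_study():
    """The standard planted-error scenario (300 mice, 3 tissues, seeded)."""
    return simulate_study(SimConfig(seed=DEFAULT_SEED))


@pytest.fixture(scope="session")
def default_pipeline(default_study):
    s = default_study
    return run_all(s.expression, s.genotypes, s.genetic_map, s.layout)


@pytest.fixture(scope="session")
def null_study():
    """Same generator, empty planted-error list."""
    return simulate_study(SimConfig(seed=DEFAULT_SEED, planted_errors=[]))


@pytest.fixture(scope="session")
def null_pipeline(null_study):
    s = null_study
    return run_all(s.expression, s.genotypes, s.genetic_map, s.layout)


@pytest.fixture
def tiny_map():
    """Two autosomes (3 + 2 markers) and an X with 2 markers."""
    return GeneticMap(
        markers=["m1", "m2", "m3", "m4", "m5", "x1", "x2"],
        chromosomes=["1", "1", "1", "2", "2", "X", "X"],
        positions=np.array([0.0, 10.0, 25.0, 0.0, 5.0, 0.0, 20.0]),
        x_chromosomes=frozenset({"X"}),
    )


@pytest.fixture
def tiny_genotypes(tiny_map):
    calls = np.array(
        [
            [0, 0, 1, 2, 2, 2, 2],
            [1, 1, 1, 0, 0, 1, 2],
            [2, -1, 2, 1, 1, 0, 0],
        ],
        dtype=np.int8,
    )
    return GenotypeTable(
        sample_ids=["s1", "s2", "s3"],
        sex=["female", "female", "male"],
        calls=calls,
        markers=list(tiny_map.markers),
    )
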