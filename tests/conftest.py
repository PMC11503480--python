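"""Shared fixtures: synthetic worlds at two scales.

The small world keeps unit/integration tests fast; the desk-scale world
and its full train/validate experiment back the end-to-end checks and
are computed once per session.
"""

import warnings

import numpy as np
import pytest

import magqc as m
from magqc.reference_db import BuildParams, build_reference_db

SMALL_WORLD_SEED = 11
DESK_WORLD_SEED = 7
EXPERIMENT_SEED = 3


@pytest.fixture(scope="session")
def small_world():
    return m.generate_synthetic_world(
        n_genomes=12,
        n_core_families=60,
        n_accessory_families=80,
        genome_length=60_000,
        n_clades=3,
        seed=SMALL_WORLD_SEED,
    )


@pytest.fixture(scope="session")
def small_db(small_world):
    return build_reference_db(small_world.reference_entries(), BuildParams())


@pytest.fixture(scope="session")
def small_model(small_world, small_db):
    """A stage-II model trained on bins simulated from the small world."""
    rng = np.random.default_rng(5)
    all_ids = {g.genome_id for g in small_world.genomes}
    bins = m.simulate_query_bins(
        small_world, all_ids, n_bins_per_genome=8, rng=rng, fragment_length=5_000
    )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        model = m.train_quality_model(bins, small_db, m.Stage2Config(seed=0))
    return model


@pytest.fixture(scope="session")
def desk_world():
    return m.generate_synthetic_world(seed=DESK_WORLD_SEED)


@pytest.fixture(scope="session")
def desk_experiment(desk_world):
    """Reference DB from the oldest date part, 20 bins/genome on the two
    recent parts, two-fold cross-validated MLP refinement."""
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return m.run_world_experiment(desk_world, seed=EXPERIMENT_SEED)
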