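import warnings

import numpy as np
import pytest

import morphnet as mn

warnings.filterwarnings("ignore", message="Objective did not converge")


@pytest.fixture(scope="session")
def parcellation():
    return mn.default_parcellation()


@pytest.fixture(scope="session")
def toy_parcellation():
    """Five-region parcellation for fast construction tests."""
    labels = tuple(f"r{i}" for i in range(5))
    return mn.ParcellationMap(
        labels=labels,
        hemispheres=("L", "L", "L", "R", "R"),
        region_names=labels,
    )


@pytest.fixture(scope="session")
def small_subject(parcellation):
    """One seeded 68-region synthetic subject with modest vertex counts."""
    spec = mn.CohortSpec(seed=5, vertex_count_range=(10, 25))
    return mn.generate_subject(spec, seed=123)


@pytest.fixture(scope="session")
def small_network(small_subject, parcellation):
    return mn.build_individual_network(small_subject, parcellation)


def random_regions(rng, V, n_max=30, d=3):
    """Random region feature sets for oracle comparisons."""
    return [
        mn.RegionFeatureSet(i, rng.standard_normal((int(rng.integers(1, n_max + 1)), d)))
        for i in range(V)
    ]
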