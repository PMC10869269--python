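"""Shared fixtures: all test inputs are generated programmatically."""

import numpy as np
import pytest

import foldscan as fs
from foldscan.fixtures import SyntheticFamilySpec, make_family


@pytest.fixture(scope="session")
def default_alphabet():
    return fs.default_alphabet()


@pytest.fixture(scope="session")
def default_matrix():
    return fs.default_substitution_matrix()


@pytest.fixture(scope="session")
def small_family_set():
    """4 families x 3 members + 4 decoys at the default study conditions."""
    return make_family(SyntheticFamilySpec(n_families=4, members_per_family=3,
                                           n_decoys=4, seed=11))


@pytest.fixture(scope="session")
def small_entries(small_family_set, default_alphabet):
    return fs.make_entries(small_family_set.chains, default_alphabet)


@pytest.fixture(scope="session")
def helix_chain():
    return fs.make_chain((("helix", 14),), seed=3)


@pytest.fixture(scope="session")
def mixed_chain():
    return fs.make_chain((("helix", 12), ("coil", 4), ("strand", 8)), seed=5)


def random_rotation(rng):
    q = rng.normal(size=4)
    q /= np.linalg.norm(q)
    w, x, y, z = q
    return np.array([
        [1 - 2 * (y * y + z * z), 2 * (x * y - w * z), 2 * (x * z + w * y)],
        [2 * (x * y + w * z), 1 - 2 * (x * x + z * z), 2 * (y * z - w * x)],
        [2 * (x * z - w * y), 2 * (y * z + w * x), 1 - 2 * (x * x + y * y)],
    ])
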