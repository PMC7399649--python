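import numpy as np
import pytest

import tractofilter as tf


@pytest.fixture(scope="session")
def toy():
    """The four-voxel / three-fiber stick-and-ball instance."""
    return tf.make_toy_example(n_dirs=30, seed=0)


@pytest.fixture(scope="session")
def toy_nnls(toy):
    return tf.solve_nnls(toy.matrix, toy.signal,
                         tf.SolverConfig(max_iter=10000, tol=1e-12))


@pytest.fixture(scope="session")
def small_phantom():
    """6 ROIs, 3 bundles, 4 fibers each — cheap ground-truth scene."""
    return tf.make_phantom(n_rois=6, n_bundles=3, fibers_per_bundle=4, seed=5)


@pytest.fixture(scope="session")
def experiment():
    """Default-size phantom experiment (6 true + 6 spliced false bundles)."""
    return tf.phantom_experiment(seed=1)


@pytest.fixture(scope="session")
def crossing_pair_phantom():
    """4-ROI phantom whose two bundles connect disjoint ROI pairs and cross,
    so both endpoint recombinations are constructible (frozen seed)."""
    ph = tf.make_phantom(n_rois=4, n_bundles=2, seed=7)
    assert sorted(ph.true_pairs) == [(1, 4), (2, 3)]
    return ph


@pytest.fixture
def rng():
    return np.random.default_rng(42)
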