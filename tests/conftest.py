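import numpy as np
import pytest

from cytozone.synthetic import SceneParams, generate_fov


SMALL_SCENE = dict(
    image_size=128,
    n_cells=3,
    cell_radius=(17.0, 22.0),
    nucleus_radius=(7.0, 10.0),
    fibril_length=(20, 50),
)


@pytest.fixture(scope="session")
def small_scene():
    """One deterministic 3-cell scene shared across tests."""
    fov, truth = generate_fov(SceneParams(seed=7, **SMALL_SCENE))
    return fov, truth


def random_histogram(rng, n_bins=256, min_nonempty=2):
    """Random sparse histogram with at least ``min_nonempty`` occupied bins."""
    k = int(rng.integers(min_nonempty, 12))
    bins = rng.choice(n_bins, size=k, replace=False)
    counts = np.zeros(n_bins, dtype=np.int64)
    counts[bins] = rng.integers(1, 500, size=k)
    return counts
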