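import numpy as np
import pytest

from treelandscape.stress import embedded_distances


@pytest.fixture(scope="session")
def embeddable_delta50():
    """Distances generated from known 2D coordinates: exactly embeddable at p=2."""
    rng = np.random.default_rng(3)
    pts = rng.uniform(0, 1, size=(50, 2))
    return pts, embedded_distances(pts)


@pytest.fixture(scope="session")
def small_landscape():
    """Clustered landscape: 3 partitions of 15 trees on 12 taxa, plus RF matrix."""
    from treelandscape.distances import rf_matrix
    from treelandscape.simulate import LandscapeSimSpec, simulate_landscape

    spec = LandscapeSimSpec(
        n_taxa=12,
        partitions=[("a", 100.0, 15), ("b", 400.0, 15), ("c", 1600.0, 15)],
        base_seed=11,
    )
    ts = simulate_landscape(spec)
    return ts, rf_matrix(ts)
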