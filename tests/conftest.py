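import numpy as np
import pytest

import aprshield as a


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def scale():
    return a.default_scale()


@pytest.fixture(scope="session")
def hsa_sequence():
    from aprshield.io import default_hsa_sequence

    return default_hsa_sequence()


def random_cluster(rng, n_beads, spread=0.6, radius=0.235):
    """A compact random protein bead cluster for SASA property tests."""
    coords = rng.normal(scale=spread, size=(n_beads, 3))
    return a.BeadFrame(
        coordinates=coords,
        radii=np.full(n_beads, radius),
        residue_index=np.arange(1, n_beads + 1),
        molecule_tag=np.full(n_beads, "protein"),
    )


@pytest.fixture
def cluster_factory(rng):
    def make(n_beads, **kwargs):
        return random_cluster(rng, n_beads, **kwargs)

    return make
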