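import numpy as np
import pytest

from enhancerlink.simulate import FixtureConfig, PlantedTr, generate_fixture


@pytest.fixture(scope="session")
def default_bundle():
    """The standard recovery fixture: 3 planted activated TRs x 60 probes."""
    return generate_fixture(FixtureConfig(seed=11))


@pytest.fixture(scope="session")
def small_bundle():
    """A small, fast bundle for IO/CLI round-trips."""
    cfg = FixtureConfig(
        seed=7,
        n_normal=10,
        n_tumor=60,
        n_probes=300,
        n_genes=320,
        n_trs=20,
        planted_activated_trs=[
            PlantedTr("G0000", n_linked_probes=15),
            PlantedTr("G0001", n_linked_probes=15),
        ],
        n_motif_windows=30,
        n_motif_planted=18,
    )
    return generate_fixture(cfg)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
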