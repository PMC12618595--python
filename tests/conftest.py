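import numpy as np
import pytest

from scfc import (
    GroundTruthMapping,
    Parcellation,
    SynthConfig,
    generate_cohort,
)


@pytest.fixture
def toy_weights():
    """3-node graph: w01=1, w12=1, w02=0.25 (lengths 1, 1, 4)."""
    return np.array(
        [[0.0, 1.0, 0.25], [1.0, 0.0, 1.0], [0.25, 1.0, 0.0]]
    )


@pytest.fixture
def parc3():
    return Parcellation.generic(3)


@pytest.fixture(scope="session")
def small_cohort():
    """12 healthy + 3 patients, 24 nodes, default mapping."""
    return generate_cohort(
        SynthConfig(seed=11, n_nodes=24, n_healthy=12, n_patients=3)
    )


@pytest.fixture(scope="session")
def noiseless_cohort():
    """10 healthy subjects, 24 nodes, zero noise and zero individuality."""
    mapping = GroundTruthMapping(noise_sd=0.0, individuality_sd=0.0)
    return generate_cohort(
        SynthConfig(seed=21, n_nodes=24, n_healthy=10, n_patients=0,
                    mapping=mapping)
    )
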