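import numpy as np
import pytest

import msocc
from msocc.data import DetectionData


@pytest.fixture(scope="session")
def small_dataset():
    """8 species x 20 sites x 6 replicates with known ground truth."""
    return msocc.generate_dataset(n_species=8, n_sites=20, seed=42)


@pytest.fixture()
def toy_detection_data():
    """2 species x 3 sites x 2 replicates, one missing cell."""
    rng = np.random.default_rng(5)
    y = rng.integers(0, 2, (2, 3, 2)).astype(np.int8)
    y[0, 1, 0] = -1
    return DetectionData(
        y=y,
        year_flag=[1, 0],
        width=rng.normal(size=3),
        distance=rng.normal(size=3),
    )


def pinned_config(u=0.0, a1=0.0, a2=0.0, v1=0.0, v2=0.0, **kwargs):
    """ModelConfig whose priors pin every species parameter near a constant.

    Hyper-sds of 1e-6 make each family's community prior a spike, so the
    sampler explores a known, fixed parameter point; detection intercepts
    are held exactly fixed.
    """
    tiny = 1e-6
    return msocc.ModelConfig(
        fixed_hypers={
            "u": (u, tiny),
            "a1": (a1, tiny),
            "a2": (a2, tiny),
        },
        fixed_detection=(v1, v2),
        **kwargs,
    )
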