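import numpy as np
import pytest

from icgflow.synthetic import (VesselTree, WashInSpec, generate_icg_video,
                               generate_vessel_tree, make_arrival_map)


@pytest.fixture(scope="session")
def tree128() -> VesselTree:
    return generate_vessel_tree(1, (128, 128), 3)


@pytest.fixture(scope="session")
def forward_video(tree128):
    """Noisy forward wash-in video with its ground truth."""
    spec = WashInSpec(make_arrival_map(tree128, "forward"),
                      direction="forward", noise_seed=1)
    return generate_icg_video(tree128, spec)


@pytest.fixture(scope="session")
def noiseless_forward_video(tree128):
    spec = WashInSpec(make_arrival_map(tree128, "forward"),
                      direction="forward", noise_sd=0.0)
    return generate_icg_video(tree128, spec)


@pytest.fixture()
def rng():
    return np.random.default_rng(0)


@pytest.fixture(scope="session")
def gaussian_blob_pair():
    """Smooth blob translated by +2 px in x; the canonical HS shift oracle."""
    x, y = np.meshgrid(np.arange(128), np.arange(128))
    f0 = 200 * np.exp(-(((x - 60) ** 2 + (y - 64) ** 2) / (2 * 12**2)))
    f1 = 200 * np.exp(-(((x - 62) ** 2 + (y - 64) ** 2) / (2 * 12**2)))
    return f0, f1, f0 > 60
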