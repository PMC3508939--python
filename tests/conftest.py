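import numpy as np
import pytest

from bicar.synth import make_blobs_dataset, make_blobs_spatial, make_blobs_temporal
from bicar.transfer import TransferConfig
from bicar.unmixing import DataMatrix


@pytest.fixture(scope="session")
def transfer_cfg() -> TransferConfig:
    return TransferConfig()


@pytest.fixture(scope="session")
def blobs_noiseless(transfer_cfg):
    """Noiseless BLOBS dataset: (X_T 16x256, X_S 16x256, GroundTruth)."""
    X_T, X_S, truth, _ = make_blobs_dataset(3, transfer=transfer_cfg)
    return X_T, X_S, truth


@pytest.fixture(scope="session")
def blobs_noisy(transfer_cfg):
    X_T, X_S, truth, snr = make_blobs_dataset(3, transfer=transfer_cfg, sigma2=0.5)
    return X_T, X_S, truth, snr


@pytest.fixture(scope="session")
def temporal_sources():
    return make_blobs_temporal(0)


@pytest.fixture(scope="session")
def spatial_sources():
    return make_blobs_spatial(0)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


def two_source_mixture(seed: int = 0, n_sensors: int = 16):
    """A noiseless 16 x 256 mixture of two known standardized waveforms."""
    sources = make_blobs_temporal(seed)[:2]
    rng = np.random.default_rng(seed + 1)
    mixing = rng.normal(size=(n_sensors, 2))
    return mixing @ sources, sources, mixing
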