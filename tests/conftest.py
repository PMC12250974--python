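import numpy as np
import pytest

from trm_maan.model import ModelConfig, build_model
from trm_maan.preprocessing import PairedSample
from trm_maan.synthetic import ModalityShift, SimConfig, make_paired_dataset


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def tiny_cfg():
    """Smallest config that exercises every architectural element."""
    return ModelConfig(D=8, n_heads=2, n_layers=1, trunk_channels=3,
                       fc_hidden=6, proj_stride=1)


@pytest.fixture
def tiny_model(tiny_cfg):
    return build_model(tiny_cfg, n_channels=3, window_len=20, seed=7)


def make_toy_samples(n_per_class: int = 4, n_channels: int = 3,
                     window_len: int = 20, seed: int = 0,
                     n_classes: int = 3) -> list[PairedSample]:
    """Trivially separable toy set: each class is a distinct constant level
    plus small noise."""
    rng = np.random.default_rng(seed)
    samples = []
    idx = 0
    for label in range(n_classes):
        for _ in range(n_per_class):
            base = float(label) * 2.0
            eeg = base + 0.1 * rng.normal(size=(n_channels, window_len))
            emg = base + 0.1 * rng.normal(size=(n_channels, window_len))
            for phase in ("odd", "even"):
                samples.append(PairedSample(eeg, emg, label, "S0", idx, phase))
            idx += 1
    return samples


@pytest.fixture
def toy_samples():
    return make_toy_samples()


@pytest.fixture(scope="session")
def small_sim_cfg():
    """Scaled-down synthetic study conditions used across tests."""
    return SimConfig(n_subjects=1, windows_per_class=8, n_channels=4,
                     rate_hz=64.0, class_band_hz=((4, 8), (8, 13), (13, 30)),
                     snr_db=10.0, seed=0,
                     modality_shift=ModalityShift(offset=2.0, scale=1.5,
                                                  extra_band_hz=(20.0, 28.0)))


@pytest.fixture(scope="session")
def small_dataset(small_sim_cfg):
    return make_paired_dataset(small_sim_cfg)
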