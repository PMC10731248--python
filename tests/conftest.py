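import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("deterministic", derandomize=True)
settings.load_profile("deterministic")

from ivimtools.model import AcquisitionScheme, IVIMParams, RicianNoiseModel, ivim_signal, rician_corrupt


@pytest.fixture(scope="session")
def scheme():
    return AcquisitionScheme()


@pytest.fixture(scope="session")
def table2_truth():
    """Cohort baseline medians as a voxel ground truth (internal units)."""
    return IVIMParams(s0=1.0, f=0.1081, d=0.95e-3, d_star=6.20e-3)


@pytest.fixture(scope="session")
def clean_table2_signal(scheme, table2_truth):
    return ivim_signal(table2_truth, scheme)


@pytest.fixture
def noisy_voxel_factory(scheme):
    """Factory producing Rician-corrupted voxel signals at a given SNR."""

    def make(truth: IVIMParams, snr: float, seed: int) -> np.ndarray:
        clean = ivim_signal(truth, scheme)
        return rician_corrupt(clean, RicianNoiseModel(truth.s0 / snr), seed)

    return make
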