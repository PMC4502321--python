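import numpy as np
import pytest

from pseudoct import MaskKind, Modality, ROIMask, Volume
from pseudoct.phantom import PhantomConfig, make_head_phantom


def make_volume(values, spacing=(1.0, 1.0, 1.0), origin=(0.0, 0.0, 0.0),
                modality=Modality.MRI):
    return Volume(np.asarray(values, dtype=float), spacing, origin, modality)


def full_mask(shape, spacing=(1.0, 1.0, 1.0), origin=(0.0, 0.0, 0.0)):
    return ROIMask(np.ones(shape, dtype=bool), spacing, origin, MaskKind.FOV_VALIDITY)


@pytest.fixture(scope="session")
def small_phantom():
    """A 48^3 noiseless phantom shared across tests that need clean anatomy."""
    cfg = PhantomConfig(shape=(48, 48, 48), spacing=(3.0, 3.0, 3.0),
                        noise_sd_ct=0.0, noise_sd_mri=0.0, bias_amplitude=0.0,
                        ct_z_keep_jitter=0.0)
    return cfg, make_head_phantom(cfg, seed=0)


@pytest.fixture(scope="session")
def noisy_phantom():
    cfg = PhantomConfig(shape=(48, 48, 48), spacing=(3.0, 3.0, 3.0))
    return cfg, make_head_phantom(cfg, seed=1)
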