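import numpy as np
import pytest

from bonefuse import (PhantomConfig, close_holes, extract_bone,
                      generate_phantom, remove_urinary_activity,
                      resample_to_grid)


def dice(a: np.ndarray, b: np.ndarray) -> float:
    return 2.0 * np.logical_and(a, b).sum() / (a.sum() + b.sum())


@pytest.fixture(scope="session")
def phantom_default():
    """Default-noise 128^3 phantom shared across tests (read-only)."""
    return generate_phantom(PhantomConfig(seed=7))


@pytest.fixture(scope="session")
def phantom_noiseless():
    return generate_phantom(PhantomConfig(seed=7, ct_noise_sigma=0.0))


@pytest.fixture(scope="session")
def segmented_phantom(phantom_default):
    """Phantom + bone mask + urinary-cleaned SPECT on the CT grid."""
    ct, spect, truth = phantom_default
    bone = close_holes(extract_bone(ct))
    spect_ct = resample_to_grid(spect, ct)
    spect_clean = remove_urinary_activity(spect_ct, bone)
    return ct, spect_clean, bone, truth
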