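import numpy as np
import pytest


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture(scope="session")
def noiseless_disk():
    """A clean unit-contrast disk phantom (image, ground-truth mask)."""
    from radstab import PhantomSpec, generate_phantom

    spec = PhantomSpec(
        lesion_axes=(30.0, 30.0),
        lesion_intensity=1.0,
        background_intensity=0.0,
        noise_sigma=0.0,
        bias_amplitude=0.0,
    )
    return generate_phantom(spec)


@pytest.fixture(scope="session")
def textured_phantom():
    """A realistic noisy, biased, textured phantom (image, mask)."""
    from radstab import PhantomSpec, generate_phantom

    spec = PhantomSpec(texture_amplitude=0.1, seed=5)
    return generate_phantom(spec)
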