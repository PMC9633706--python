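import numpy as np
import pytest

from roentgan.phantom import PhantomParams, class_params, generate_phantom


@pytest.fixture(scope="session")
def small_phantom():
    """One sharp, noiseless 64-pixel phantom."""
    return generate_phantom(PhantomParams(image_size=64, joint_gap=10.0,
                                          noise_sd=0.0, seed=7))


@pytest.fixture(scope="session")
def phantom_stack_64():
    """64 small two-class phantoms with mild noise, as uint8 arrays."""
    rng = np.random.default_rng(0)
    base = PhantomParams(image_size=64, joint_gap=10.0, noise_sd=3.0)
    imgs = []
    for label in ("A", "B"):
        for _ in range(32):
            p = class_params(label, base=base, seed=int(rng.integers(2 ** 31)))
            imgs.append(generate_phantom(p))
    return imgs
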