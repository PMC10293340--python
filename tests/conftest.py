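import numpy as np
import pytest

from fetalvol.phantom import PhantomSpec, generate_phantom


@pytest.fixture(scope="session")
def small_spec():
    """A down-scaled gravid-uterus scene that generates in well under a second."""
    return PhantomSpec(seed=11, fetal_scale=0.45)


@pytest.fixture(scope="session")
def small_phantom(small_spec):
    return generate_phantom(small_spec)


@pytest.fixture(scope="session")
def clean_small_phantom():
    """Noise- and bias-free variant for tests that need exact intensities."""
    spec = PhantomSpec(seed=11, fetal_scale=0.45, noise_sigma=0.0, bias_field_amp=0.0)
    return generate_phantom(spec)


@pytest.fixture(scope="session")
def tiny_training_set():
    """Four very small noisy phantoms plus one held-out, for training tests."""
    from fetalvol.phantom import cohort_specs

    specs = cohort_specs(5, seed=42, scale_range=(0.42, 0.52))
    cases = [generate_phantom(s) for s in specs]
    return cases[:4], cases[4]


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
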