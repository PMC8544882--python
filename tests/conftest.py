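import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "default",
    derandomize=True,
    database=None,
    max_examples=100,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def zero_noise_bundle():
    """A small zero-instrument-noise bundle: exact inverse-construction oracle."""
    from coralith.synth import default_species_profiles, generate_raw_measurements

    profiles = default_species_profiles()
    for p in profiles:
        p.measurement_noise = {k: 0.0 for k in p.measurement_noise}
    return generate_raw_measurements(profiles, n_per_species=3, seed=11)


@pytest.fixture(scope="session")
def default_bundle():
    """The standard 5 species x 10 specimens x 2 sets bundle with default noise."""
    from coralith.synth import generate_raw_measurements

    return generate_raw_measurements(n_per_species=10, seed=42)
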