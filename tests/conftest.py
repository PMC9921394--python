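import numpy as np
import pytest

from reptrack.signals import ActivityLabel
from reptrack.simulate import GeneratorConfig, generate_dataset


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def fast_config():
    """Generator config with shortened breaks for cheap unit tests.

    Break and occurrence statistics keep their minima (which the
    post-processing thresholds assume) but are capped to keep recordings
    short; everything else is the study default.
    """
    return GeneratorConfig(
        break_duration_range=(63, 200),
        occurrence_duration_range={
            ActivityLabel.DIP: (135, 400),
            ActivityLabel.PULLUP: (91, 400),
            ActivityLabel.SQUAT: (157, 400),
        },
        rep_count_range={
            ActivityLabel.DIP: (2, 5),
            ActivityLabel.PULLUP: (1, 5),
            ActivityLabel.SQUAT: (2, 5),
        },
    )


@pytest.fixture(scope="session")
def clean_config(fast_config):
    """Noise-free variant of the fast config (deterministic waveforms)."""
    import dataclasses
    return dataclasses.replace(fast_config, noise_sd=0.0, transient_rate=0.0)


@pytest.fixture(scope="session")
def tiny_corpus(fast_config):
    return generate_dataset(fast_config, 4, seed=99)
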