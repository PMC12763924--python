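import numpy as np
import pytest

from mvpatrial.synth import TrialConfig, generate_trial


@pytest.fixture(scope="session")
def small_trial():
    """A small traditional-descriptor trial with a strong injected pattern."""
    cfg = TrialConfig(
        descriptors=("traditional",),
        n_preschools=30,
        children_per_preschool=14,
        effects={
            "7mo": {"sed": -12.0, "lpa": 6.0, "mpa": 2.8, "vpa": 2.8},
            "18mo": {"sed": -10.0, "lpa": 5.0, "mpa": 2.4, "vpa": 2.4},
        },
    )
    return generate_trial(cfg, seed=42)


@pytest.fixture(scope="session")
def null_trial():
    """A small trial with no intervention effect."""
    cfg = TrialConfig(
        descriptors=("traditional",), n_preschools=20, children_per_preschool=12
    )
    return generate_trial(cfg, seed=7)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
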