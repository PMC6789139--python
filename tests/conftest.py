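import numpy as np
import pytest

from raphequant import cellcount, synth


@pytest.fixture(scope="session")
def clean_section():
    """A clutter-free two-channel section with 200 planted somata (p=0.5)."""
    spec = synth.SectionSpec(p_coexpress=0.5, cells_per_subregion=50,
                             clutter_density=0.0, seed=42)
    section, truth = synth.make_section(spec)
    return spec, section, truth


@pytest.fixture(scope="session")
def fixed_policy():
    """Absolute threshold at the midpoint of the planted bg/fg levels."""
    return cellcount.DetectionPolicy(threshold=0.425)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
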