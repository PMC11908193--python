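import numpy as np
import pytest

from rydmr.imaging import effect_maps
from rydmr.spin_core import RadicalPairSystem
from rydmr.synthgen import PhantomSpec, gen_worm_stack


@pytest.fixture(scope="session")
def one_proton():
    """Single proton on radical 1: the minimal resonance test system."""
    return RadicalPairSystem(hf1=(1.0,), hf2=())


@pytest.fixture(scope="session")
def default_system():
    return RadicalPairSystem()


@pytest.fixture(scope="session")
def phantom():
    """Default worm phantom stack plus ground truth (shared, read-only)."""
    return gen_worm_stack(PhantomSpec(seed=1))


@pytest.fixture(scope="session")
def phantom_maps(phantom):
    stack, _ = phantom
    return effect_maps(stack)
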