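import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # make _oracles importable

from ganglion3d import generate_scene, preset_params


@pytest.fixture(scope="session")
def separated_scene():
    """Well-separated high-SNR scene: the exact-recovery regime."""
    return generate_scene(preset_params("separated", seed=11))


@pytest.fixture(scope="session")
def touching_scene():
    """Scene with 5 engineered touching pairs for splitting tests."""
    return generate_scene(preset_params("touching", seed=7))


@pytest.fixture(scope="session")
def two_region_scene():
    """Balanced NSRR/FRR scene for classification and shape contrasts."""
    return generate_scene(preset_params("two-region", seed=5))


@pytest.fixture
def rng():
    return np.random.default_rng(42)
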