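import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # make oracles importable


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def block_scores():
    """Noiseless 17-item, 2-block score matrix with known partition."""
    from opnmfkit import generate_scores

    sm, truth = generate_scores(p=17, k=2, n=120, noise_sd=0.0, seed=99)
    return sm, truth
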