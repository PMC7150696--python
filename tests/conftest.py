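import numpy as np
import pytest

import fastscan as fs


@pytest.fixture(scope="session")
def truth_small():
    """Default-texture specimen at a small frame size."""
    return fs.make_ground_truth(128, 160, seed=3)


@pytest.fixture(scope="session")
def granular_small():
    """Fine-grained specimen (pixel-scale detail), small frame."""
    return fs.make_ground_truth(128, 160, {"preset": "granular"}, seed=3)


def noisy_pair(truth, snr, seed):
    """Two same-view frames of ``truth`` with independent noise at ``snr``."""
    noise = fs.NoiseModel.for_target_snr(truth.pixels, snr, seed=seed)
    stack = fs.simulate_stack(truth, None, None, noise, None, 2, seed=seed)
    return stack.frames[0], stack.frames[1]
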