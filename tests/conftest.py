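import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # make oracles importable


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


@pytest.fixture()
def disc_mask():
    """Filled disc of radius 20 centered in an 80x80 frame."""
    yy, xx = np.mgrid[:80, :80]
    return (yy - 40) ** 2 + (xx - 40) ** 2 <= 20**2
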