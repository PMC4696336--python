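import sys
from pathlib import Path

import numpy as np
import pytest

# make the sibling oracle helpers importable regardless of invocation dir
sys.path.insert(0, str(Path(__file__).parent))


@pytest.fixture
def rng():
    return np.random.default_rng(20260924)


@pytest.fixture
def rect_blob_field():
    """Noise-free white field with one dark 5x10 rectangle (area 50 px^2)."""
    img = np.full((64, 64), 255, dtype=np.uint8)
    img[20:25, 10:20] = 60
    return img
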