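import numpy as np
import pytest

from standcount.geometry import Box


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


def random_box(rng, span: float = 100.0, min_side: float = 2.0) -> Box:
    """A random valid box inside a span x span region."""
    x0, y0 = rng.uniform(0, span, size=2)
    w, h = rng.uniform(min_side, span / 2, size=2)
    return Box(x0, y0, x0 + w, y0 + h)
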