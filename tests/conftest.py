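import numpy as np
import pytest


@pytest.fixture
def checker4() -> np.ndarray:
    """4x4 black/white checkerboard, 8-bit."""
    rr, cc = np.indices((4, 4))
    return np.where((rr + cc) % 2 == 0, 0, 255).astype(np.uint8)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)


def random_patches(n: int, sizes=(2, 3, 4, 5, 6, 7, 8), seed: int = 0):
    """Seeded normalized patches cycling over the given side lengths."""
    gen = np.random.default_rng(seed)
    out = []
    for i in range(n):
        p = sizes[i % len(sizes)]
        out.append(gen.integers(0, 256, size=(p, p)) / 255.0)
    return out
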