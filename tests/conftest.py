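import numpy as np
import pytest

from endoquant import Detection, Mask, SceneSpec, generate_scene


def random_mask(rng, frame=40, max_side=12) -> Mask:
    """Small random blob mask for property tests."""
    while True:
        h = int(rng.integers(2, max_side))
        w = int(rng.integers(2, max_side))
        pix = rng.random((h, w)) < 0.6
        if pix.any():
            r = int(rng.integers(0, frame - h))
            c = int(rng.integers(0, frame - w))
            return Mask(pix, (r, c))


@pytest.fixture(scope="session")
def small_scene():
    """A modest noiseless scene shared by detector and pipeline tests."""
    return generate_scene(SceneSpec(n_objects=30, noise_sd=0.0, seed=11))


@pytest.fixture(scope="session")
def noisy_scene():
    return generate_scene(SceneSpec(n_objects=40, seed=7))


@pytest.fixture()
def rng():
    return np.random.default_rng(42)


def square_mask(side: int, offset=(0, 0), label="buchnera") -> Mask:
    return Mask(np.ones((side, side), dtype=bool), offset, label)


def square_detection(side: int, offset=(0, 0), score=0.9) -> Detection:
    return Detection(square_mask(side, offset), score=score)
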