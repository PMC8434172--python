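import numpy as np
import pytest

from usconf import nn
from usconf.phantom import PhantomSpec, generate_dataset


def tiny_cnn(seed: int) -> nn.Sequential:
    """A seeded 2-conv-layer network on 8x8 inputs, 3 classes."""
    rng = np.random.default_rng(seed)
    return nn.Sequential([
        nn.Conv2D(1, 3, 3, rng), nn.ReLU(),
        nn.Conv2D(3, 4, 3, rng), nn.ReLU(),
        nn.GlobalAvgPool(), nn.Linear(4, 3, rng),
    ])


SMALL_SPEC = PhantomSpec(
    height_px=96, width_px=64, axial_res=0.04, lateral_res=0.04,
    epidermis_top_mm=1.0, tumor_center_mm=2.2, tumor_radius_mm=0.5,
    muscle_top_mm=3.5,
)


@pytest.fixture(scope="session")
def small_cohort():
    """24 reduced-size phantoms (6 per class, 2 patients per class)."""
    return generate_dataset(6, 2, seed=5, base_spec=SMALL_SPEC)


class ScriptedRng:
    """Deterministic stand-in for np.random.Generator in augmentation tests:
    plays back queued uniform/integer draws."""

    def __init__(self, randoms, integer_pairs, uniforms=()):
        self._randoms = list(randoms)
        self._ints = list(integer_pairs)
        self._uniforms = list(uniforms)

    def random(self):
        return self._randoms.pop(0)

    def integers(self, lo, hi, size=None):
        return np.array(self._ints.pop(0))

    def uniform(self, lo, hi):
        return self._uniforms.pop(0)
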