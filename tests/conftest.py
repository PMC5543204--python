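import numpy as np
import pytest

from fishmfa.synthetic import SyntheticSpec, generate_scene

# Half of the 1016 x 896 reference resolution: large enough for realistic
# nucleus geometry, small enough to keep the suite quick.
HALF_SHAPE = (508, 448)
HALF_RADII = (12.0, 16.0)


def half_scale_spec(**overrides) -> SyntheticSpec:
    kwargs = dict(image_size=HALF_SHAPE, n_nuclei=20, radius_range=HALF_RADII, seed=1)
    kwargs.update(overrides)
    return SyntheticSpec(**kwargs)


@pytest.fixture(scope="session")
def uniform_scene():
    """Evenly illuminated half-scale scene with 20 nuclei."""
    return generate_scene(half_scale_spec())


@pytest.fixture(scope="session")
def gradient_scene():
    """Half-scale scene under the 0.35 -> 1.0 illumination ramp."""
    return generate_scene(half_scale_spec(illumination_gradient=(0.35, 1.0)))


@pytest.fixture(scope="session")
def uniform_segmentation(uniform_scene):
    from fishmfa.segmentation import segment_nuclei

    rgb, _ = uniform_scene
    return segment_nuclei(rgb)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(12345)
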