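import numpy as np
import pytest

from nucannotate import fixtures
from nucannotate.core import IntensityImage


@pytest.fixture
def small_spec():
    """A quick-to-render field: a few singles, one pair, some debris."""
    return fixtures.SyntheticSpec(
        image_height=192,
        image_width=192,
        n_single=5,
        n_touching_pairs=1,
        n_clusters=0,
        n_debris=2,
        seed=11,
    )


@pytest.fixture
def small_field(small_spec):
    return fixtures.generate_field(small_spec)


@pytest.fixture
def singles_field():
    """Ten isolated single nuclei with tight size spread and low noise."""
    spec = fixtures.SyntheticSpec(
        image_height=384,
        image_width=384,
        n_single=10,
        n_touching_pairs=0,
        n_clusters=0,
        n_debris=0,
        nucleus_radius_sd=1.0,
        seed=7,
    )
    return spec, *fixtures.generate_field(spec)


def make_image(arr, bit_depth=8):
    return IntensityImage(np.asarray(arr), bit_depth)
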