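import numpy as np
import pytest

from earbox import SyntheticEarSpec, generate_ear
from earbox.synthetic import archetype_spec


@pytest.fixture(scope="session")
def default_spec():
    return SyntheticEarSpec(seed=1)


@pytest.fixture(scope="session")
def default_ear(default_spec):
    """One fully-set ear with pseudo renders, shared across test modules."""
    return generate_ear(default_spec, ear_id="fixture")


@pytest.fixture(scope="session")
def arch2_ear(default_spec):
    """Apically aborted (30%) archetype-2 ear."""
    spec = archetype_spec(2, default_spec.replace(seed=7))
    return spec, generate_ear(spec, render_pseudo=False, ear_id="arch2")


@pytest.fixture(scope="session")
def barren_ear(default_spec):
    """Fully aborted ear: bare cob, no grains."""
    spec = archetype_spec(5, default_spec)
    return spec, generate_ear(spec, ear_id="barren")


def rect_mask(n_rows=100, n_cols=40, height=120, width=60, top=10, left=10):
    """A filled axis-aligned rectangle inside a larger blank raster."""
    mask = np.zeros((height, width), dtype=bool)
    mask[top:top + n_rows, left:left + n_cols] = True
    return mask
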