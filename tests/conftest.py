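import numpy as np
import pytest

import sdmlite as sl
from sdmlite.grids import ClimateStack


def make_stack(arrays, codes=None, x0=0.0, y0=0.0, cellsize=1.0):
    """Build a small ClimateStack from 2-D arrays (NaN = nodata)."""
    arrays = np.asarray(arrays, dtype=float)
    if arrays.ndim == 2:
        arrays = arrays[None]
    if codes is None:
        codes = [f"v{i + 1}" for i in range(arrays.shape[0])]
    return ClimateStack(list(codes), arrays.copy(), x0, y0, cellsize)


@pytest.fixture(scope="session")
def fixture_bundle():
    """The packaged virtual-species study bundle, regenerated from its config."""
    config, stack, species, occ = sl.load_default_fixture()
    return config, stack, species, occ


@pytest.fixture(scope="session")
def fixture_tables(fixture_bundle):
    """Presence and background sample matrices on the default fixture."""
    _, stack, _, occ = fixture_bundle
    presence = sl.extract_values(stack, occ.points, label=1)
    bg_points = sl.sample_background(stack, 2000, seed=42)
    background = sl.extract_values(stack, bg_points, label=0)
    return presence, background
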