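import numpy as np
import pytest

import phmri
from phmri import AtlasVolume, BoldScan


@pytest.fixture(scope="session")
def small_atlas() -> AtlasVolume:
    """Six-region Voronoi atlas on a 16x16x8 grid."""
    return phmri.generate_atlas(6, (16, 16, 8), seed=11)


@pytest.fixture(scope="session")
def study_atlas() -> AtlasVolume:
    """Desk-scale study atlas: 40 regions, ~6,000 in-brain voxels."""
    return phmri.generate_atlas(40, (32, 32, 16), seed=7)


def make_scan(
    data: np.ndarray,
    tr: float = 1.0,
    mask: np.ndarray | None = None,
    **kwargs,
) -> BoldScan:
    """Wrap a raw 4D array into a BoldScan with an all-true mask."""
    if mask is None:
        mask = np.ones(data.shape[:3], dtype=bool)
    return BoldScan(data=data, tr_seconds=tr, mask=mask, **kwargs)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(2024)
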