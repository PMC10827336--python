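import numpy as np
import pytest
from scipy import ndimage

import speckletrack as st


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def textured_image():
    """A smooth random texture with a bright blob target at (100, 100)."""
    r = np.random.default_rng(0)
    base = ndimage.gaussian_filter(r.standard_normal((200, 200)), 2)
    yy, xx = np.mgrid[0:200, 0:200]
    blob = np.exp(-((xx - 100) ** 2 + (yy - 100) ** 2) / (2 * 15.0**2))
    return base * 0.3 + blob


@pytest.fixture(scope="session")
def two_region_sequence():
    """Simulated scene: fast tissue, one static 1-cm circular lesion."""
    cfg = st.SimulationConfig(
        shape=(160, 160),
        tissue_tau=0.1,
        lesion_geometries=(st.CircleRoi(80, 80, 20, id="C1"),),
        n_frames=3,
        exposure_substeps=8,
        seed=42,
    )
    return st.simulate_sequence(cfg)
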