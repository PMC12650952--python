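import numpy as np
import pytest

import digichamber as dc


@pytest.fixture(scope="session")
def small_geometry():
    """A 20 x 20 = 400 chamber chip; fast to render, same optics as default."""
    return dc.ChipGeometry(n_rows=20, n_cols=20)


@pytest.fixture(scope="session")
def small_chip(small_geometry):
    """Noise-free rendered chip at 3.6 pM with its ground truth."""
    truth = dc.simulate_loading(3.6e-12, small_geometry, seed=11)
    frame = dc.render_frame(truth, small_geometry, time_min=30.0,
                            noise=dc.NOISELESS, seed=11)
    return truth, frame


def rog_brute_force(crop):
    """Independent ROG oracle: explicit double loop over the moment sums."""
    crop = np.asarray(crop, dtype=float)
    m, n = crop.shape
    m00 = m20 = m02 = 0.0
    for y in range(m):
        for x in range(n):
            g = crop[y, x]
            m00 += g
            m20 += (x - (n - 1) / 2.0) ** 2 * g
            m02 += (y - (m - 1) / 2.0) ** 2 * g
    return np.sqrt((m20 + m02) / m00)
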