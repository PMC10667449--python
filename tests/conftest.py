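import numpy as np
import pytest

from tiscout import ScoutImage, ScoutSeries, ShimBox


def make_series(arrays, ti_ms, shim=None, max_pi=4095, series_id="test"):
    """Build a ScoutSeries from a list of 2-D integer arrays."""
    arrays = [np.asarray(a, dtype=np.int64) for a in arrays]
    if shim is None:
        rows, cols = arrays[0].shape
        shim = ShimBox(1, 1, cols - 2, rows - 2)
    images = tuple(ScoutImage(a, t, max_pi) for a, t in zip(arrays, ti_ms))
    return ScoutSeries(images, shim, series_id=series_id)


def random_series(rng, n_images=3, shape=(32, 32), max_pi=255, shim=None):
    """Random integer-valued series for oracle-equivalence tests."""
    arrays = [rng.integers(0, max_pi + 1, size=shape) for _ in range(n_images)]
    ti = [60.0 + 10.0 * i for i in range(n_images)]
    return make_series(arrays, ti, shim=shim, max_pi=max_pi)


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)
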