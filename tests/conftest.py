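import numpy as np
import pytest

from tribomove.simulate import CrwParams, gen_crw_replicate


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture
def small_replicate(rng):
    """A short paper-scale replicate: 10 CRW beetles, 20 s at 25 fps."""
    params = CrwParams(duration_s=20.0, n_individuals=10)
    meta = {
        "replicate_id": "rep1", "line_id": "H01", "regime": "high",
        "block_id": "1", "camera_id": "3",
    }
    return gen_crw_replicate(params, meta, rng)


def make_track_xy(rng, n_points=50, step=3.0, kappa=4.0):
    """Smooth random polyline for oracle comparisons (plain array)."""
    turns = rng.vonmises(0.0, kappa, size=n_points - 1)
    turns[0] = rng.uniform(-np.pi, np.pi)
    headings = np.cumsum(turns)
    steps = rng.gamma(9.0, step / 9.0, size=n_points - 1)
    xy = np.zeros((n_points, 2))
    xy[1:, 0] = np.cumsum(steps * np.cos(headings))
    xy[1:, 1] = np.cumsum(steps * np.sin(headings))
    return xy
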