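import numpy as np
import pandas as pd
import pytest

from septrack.simulate import SimCellConfig, simulate_cell_population


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def one_cell():
    """A single 4 x 1 µm spherocylindrical cell."""
    return simulate_cell_population(
        SimCellConfig(n_cells=1, length_mean=4.0, length_sd=0.0, width=1.0,
                      septum_prob=0.0, seed=0)
    )[0]


def make_track(track_id, frames, xs, ys, cell_id=None):
    return pd.DataFrame(
        {
            "track_id": track_id,
            "frame": frames,
            "x_um": xs,
            "y_um": ys,
            "cell_id": cell_id,
        }
    )


@pytest.fixture
def make_track_df():
    return make_track
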