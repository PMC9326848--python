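import numpy as np
import pytest

from colocal.data_model import CellImage, ImageSet, Window
from colocal.simulate import SimConfig, simulate_study


@pytest.fixture()
def window100():
    return Window(0, 100, 0, 100)


@pytest.fixture()
def one_pair_image(window100):
    """One i-cell at (50,50) and one j-cell at (53,54): distance 5."""
    return CellImage("img", [50.0, 53.0], [50.0, 54.0], ["i", "j"], window100)


def random_image(rng, n_i=25, n_j=25, side=1000.0, image_id="img"):
    win = Window(0, side, 0, side)
    x = rng.uniform(0, side, n_i + n_j)
    y = rng.uniform(0, side, n_i + n_j)
    marks = np.array(["i"] * n_i + ["j"] * n_j, dtype=object)
    return CellImage(image_id, x, y, marks, win)


@pytest.fixture(scope="session")
def small_cfg():
    """Reduced study geometry for unit tests (not the benchmark design)."""
    return SimConfig(n_subjects=8, images_per_subject=2,
                     cell_count_choices=(50, 100, 150, 200), density_grid=64)


@pytest.fixture(scope="session")
def small_study(small_cfg):
    study, truth = simulate_study(small_cfg, regime="difference", seed=11)
    return study, truth


@pytest.fixture(scope="session")
def small_null_study(small_cfg):
    study, truth = simulate_study(small_cfg, regime="null", seed=12)
    return study, truth
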