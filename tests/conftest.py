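import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

import rzscreen as rz

settings.register_profile(
    "ci", derandomize=True, max_examples=50,
    suppress_health_check=[HealthCheck.too_slow], deadline=None)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def small_screen():
    """Scaled-down synthetic screen shared across tests (seed 1)."""
    cfg = rz.ScreenConfig.scaled_down(seed=1)
    screen, truth = rz.simulate_screen(cfg)
    return screen, truth, cfg


@pytest.fixture(scope="session")
def small_tensor(small_screen):
    screen, truth, cfg = small_screen
    return rz.build_signature_tensor(screen), truth


def make_plate(n_genes=10, n_vehicle=5, treatments=("drugA",),
               cell="cellX", plate="P1", seed=0, group="CCL"):
    """Minimal single-plate screen with explicit well values."""
    rng = np.random.default_rng(seed)
    wells, rows = [], []
    for i in range(n_vehicle):
        wells.append((f"{plate}:V{i}", plate, "PH0", cell, group,
                      rz.io.VEHICLE, 10.0))
    for j, drug in enumerate(treatments):
        wells.append((f"{plate}:T{j}", plate, "PH0", cell, group,
                      drug, 10.0))
    ann = pd.DataFrame(wells, columns=rz.io.PLATE_ANNOTATION_COLUMNS)
    values = rng.normal(5, 1, (n_genes, len(wells)))
    genes = [f"g{i}" for i in range(n_genes)]
    matrix = rz.GctMatrix(pd.DataFrame(values, index=genes,
                                       columns=ann["well_id"]))
    return rz.ExpressionScreen(matrix, ann)


@pytest.fixture
def single_plate_screen():
    return make_plate()
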