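"""Shared fixtures: small seeded synthetic datasets."""

import numpy as np
import pandas as pd
import pytest

from occupam import covariates as cov
from occupam import synth

YEARS = [2021, 2022, 2023, 2024]


def make_dataset(n_cells=120, n_forests=3, seed=1, years=YEARS, sigma=0.5,
                 forest_jitter=True, fire_rate=3.0, params=None):
    """Simulate landscape -> fires -> occupancy -> detections -> design."""
    cells = synth.gen_landscape(n_cells, n_forests, seed=seed)
    burns = synth.gen_fire_history(cells, range(1985, years[-1] + 1),
                                   fire_rate=fire_rate, seed=seed + 1)
    if params is None:
        params = synth.paper_like_params(
            n_forests, sigma=sigma, forest_jitter=forest_jitter,
            rng=np.random.default_rng(seed + 2))
    truth = synth.simulate_occupancy(cells, burns, params, years, seed=seed + 3)
    dep = synth.gen_deployments(cells, years, seed=seed + 4)
    events, truth_hist = synth.simulate_detections(truth, dep, params, seed=seed + 5)
    design = cov.build_design(cells, burns, truth_hist)
    return {"cells": cells, "burns": burns, "params": params, "truth": truth,
            "deployments": dep, "events": events, "history": truth_hist,
            "design": design}


@pytest.fixture(scope="session")
def small_dataset():
    return make_dataset(n_cells=120, n_forests=3, seed=1)


@pytest.fixture(scope="session")
def tiny_cells():
    return synth.gen_landscape(20, 2, seed=7)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
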