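"""Shared fixtures: a small synthetic study all stages can run on."""

import numpy as np
import pytest

from nhpikit.natal import assign_natal_habitats, compute_score_grid
from nhpikit.synthetic import LandscapeConfig, generate_landscape, place_nests


@pytest.fixture(scope="session")
def landscape():
    return generate_landscape(LandscapeConfig(n_rows=100, n_cols=100), seed=11)


@pytest.fixture(scope="session")
def nests(landscape):
    df = place_nests(landscape, 10, spacing_min=1500.0, seed=3)
    return {r.individual: (r.nest_x, r.nest_y) for r in df.itertuples()}


@pytest.fixture(scope="session")
def natal_stage(landscape, nests):
    assignments, pca = assign_natal_habitats(landscape, nests)
    return {a.individual: a for a in assignments}, pca


@pytest.fixture(scope="session")
def score_grid(landscape, natal_stage):
    _, pca = natal_stage
    return compute_score_grid(landscape, pca)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
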