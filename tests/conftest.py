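"""Shared fixtures: small synthetic landscapes generated at test time."""

import numpy as np
import pytest

from elcgap.synthetic import SyntheticLandscapeSpec, generate_raster_stack

SMALL_N_VARS = {"bioclimatic": 4, "edaphic": 3, "geophysic": 3}


def small_spec(**overrides) -> SyntheticLandscapeSpec:
    """A quick-to-generate landscape spec (~50x50 cells, 3 zones/component)."""
    params = dict(
        extent=(-4.0, 39.0, -3.5, 39.5),
        cell_size=0.01,
        n_vars=dict(SMALL_N_VARS),
        noise_sd=0.3,
        seed=42,
    )
    params.update(overrides)
    return SyntheticLandscapeSpec(**params)


@pytest.fixture(scope="session")
def landscape():
    """(stack, truth) for a small noisy landscape shared across tests."""
    return generate_raster_stack(small_spec())


@pytest.fixture(scope="session")
def quiet_landscape():
    """(stack, truth) for a zero-noise landscape: values equal zone means."""
    return generate_raster_stack(small_spec(noise_sd=0.0, seed=7))


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
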