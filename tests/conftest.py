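"""Shared fixtures.

The replicate grids are expensive (hundreds of Wright-Fisher burn-ins), so
they are session-scoped and shared across test modules.  Grid runs use the
diffusion-preserving extra rescale (total factor 100: scaled Ne = 100,
2000-generation burn-in) with 10 replicates per recombination multiplier;
theta, rho and Ne*s match the canonical x25 conditions.  Problem sizes are
documented in docs/methods.md.
"""

import numpy as np
import pytest
from hypothesis import settings

from chromdiv import default_parameters, scale_parameters
from chromdiv.sim_config import diffusion_rescale
from chromdiv.wf_engine import ancestral_diversity_grid

settings.register_profile("ci", derandomize=True, deadline=None, max_examples=25)
settings.load_profile("ci")

GRID_SEED = 20260926
GRID_REPLICATES = 10
EXTRA_RESCALE = 4


@pytest.fixture(scope="session")
def selection_grid():
    """Per-replicate pi by region: selection on, gene conversion off,
    smallest ancestral population, all nine multipliers."""
    sp = diffusion_rescale(
        default_parameters(ancestral_Ne_diploids=10_000), EXTRA_RESCALE
    )
    df = ancestral_diversity_grid(sp, n_replicates=GRID_REPLICATES, seed=GRID_SEED)
    df.attrs["params"] = sp
    return df


@pytest.fixture(scope="session")
def gene_conversion_grid():
    """As selection_grid but with gene conversion at r/3, 440-bp tracts."""
    sp = diffusion_rescale(
        default_parameters(ancestral_Ne_diploids=10_000, gene_conversion_enabled=True),
        EXTRA_RESCALE,
    )
    df = ancestral_diversity_grid(sp, n_replicates=GRID_REPLICATES, seed=GRID_SEED + 1)
    df.attrs["params"] = sp
    return df


@pytest.fixture(scope="session")
def neutral_grid():
    """Neutral-model grid: pi should sit at theta for every multiplier."""
    sp = diffusion_rescale(
        default_parameters(ancestral_Ne_diploids=10_000, selection_mode="neutral"),
        EXTRA_RESCALE,
    )
    df = ancestral_diversity_grid(sp, n_replicates=3, seed=GRID_SEED + 2)
    df.attrs["params"] = sp
    return df


@pytest.fixture(scope="session")
def small_rng():
    return np.random.default_rng(12345)
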