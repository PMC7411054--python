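"""Shared fixtures: small synthetic screens sized for fast tests."""

import pytest

from phenoprofiler import ScreenConfig
from phenoprofiler.pipeline import run_pipeline
from phenoprofiler.synthgen import simulate_screen


def fast_config(seed: int = 11, **overrides) -> ScreenConfig:
    """A small but structurally complete screen: 3 coherent MoAs, redundant
    blocks, noise features, one plate per batch."""
    params = dict(
        n_compounds=30,
        n_moas=3,
        moa_size_distribution=[3, 3, 3],
        frac_multi_moa=0.0,
        n_incoherent_moas=0,
        n_features=24,
        n_redundant_blocks=2,
        redundant_block_size=2,
        n_noise_features=6,
        cells_per_well_mean=150.0,
        cells_per_well_size=30.0,
        seed=seed,
    )
    params.update(overrides)
    return ScreenConfig(**params)


@pytest.fixture(scope="session")
def small_config():
    return fast_config()


@pytest.fixture(scope="session")
def small_screen(small_config):
    return simulate_screen(small_config)


@pytest.fixture(scope="session")
def small_result(small_config):
    """Full pipeline run on the small screen (no permutations)."""
    return run_pipeline(small_config, n_perm=0)
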