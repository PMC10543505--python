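"""Shared fixtures: small seeded synthetic datasets."""
import numpy as np
import pytest
from hypothesis import settings

from multigrn import SimConfig, simulate_cells, simulate_grn

settings.register_profile("deterministic", derandomize=True,
                          deadline=None)
settings.load_profile("deterministic")


def small_config(**overrides) -> SimConfig:
    base = dict(
        n_tfs=6, n_targets=40, n_peaks=120, n_cells_per_condition=150,
        n_triples=18, n_master_tfs=2, master_targets=5,
        chrom_length=4_000_000, seed=0,
    )
    base.update(overrides)
    return SimConfig(**base)


@pytest.fixture(scope="session")
def small_sim():
    cfg = small_config()
    grn = simulate_grn(cfg)
    ds = simulate_cells(grn, cfg)
    return cfg, grn, ds


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
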