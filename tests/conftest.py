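"""Shared fixtures: one small synthetic genome reused across test modules."""

import numpy as np
import pytest

import epimutkit as ek


def small_sim_config(seed: int = 1) -> ek.SimConfig:
    cfg = ek.SimConfig(
        seed=seed,
        n_cpgs=3000,
        n_genes=60,
        n_chroms=2,
        chrom_length=400_000,
    )
    for p in cfg.cell_profiles:
        p.n_planted_dmcs //= 5
        p.n_planted_degs = max(2, p.n_planted_degs // 5)
    return cfg


@pytest.fixture(scope="session")
def sim_config() -> ek.SimConfig:
    return small_sim_config()


@pytest.fixture(scope="session")
def genome(sim_config) -> ek.GenomeModel:
    return ek.simulate_genome(sim_config)


@pytest.fixture(scope="session")
def half_site_hits(genome) -> list:
    return ek.scan_motif(genome.sequence, "AGGTCA", name="ERE_half_site")


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
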