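import numpy as np
import pandas as pd
import pytest

from bridgefinder import simulate


@pytest.fixture(scope="session")
def paper_composition_config() -> simulate.SimConfig:
    """Config whose sample bookkeeping mirrors the emulated two-platform
    study (329 + 388 samples, extraneous categories on platform B only)."""
    return simulate.SimConfig(seed=7)


@pytest.fixture(scope="session")
def small_sim(paper_composition_config):
    return simulate.generate_expression(paper_composition_config)


def three_module_config(
    seed: int,
    n_per_group: int = 100,
    within_cor: float = 0.8,
    module_size: int = 60,
) -> simulate.SimConfig:
    """Three planted modules, no background genes, single platform, the
    first module carrying a negative disease shift."""
    return simulate.SimConfig(
        seed=seed,
        n_genes=3 * module_size,
        module_sizes=(module_size,) * 3,
        within_module_cor=within_cor,
        trait_effect={0: {"MCI": -1.0}, 1: {}, 2: {}},
        group_counts={"A": {"CTL": n_per_group, "MCI": n_per_group}, "B": {}},
        probes_per_gene={1: 1.0},
        probe_noise_sd=0.0,
        n_unmapped_probes=0,
        batch_offsets=0.0,
        batch_scale=1.0,
    )


def gene_level_matrix(config: simulate.SimConfig) -> tuple[pd.DataFrame, pd.DataFrame, simulate.GroundTruth]:
    """Platform-A gene-level expression (single probe per gene, no probe
    noise) with its metadata and ground truth."""
    sim = simulate.generate_expression(config)
    matrix = sim.platform_a.copy()
    matrix.index = [sim.probe_to_gene_a[p] for p in matrix.index]
    meta = sim.metadata[sim.metadata["platform"] == "A"].reset_index(drop=True)
    return matrix, meta, sim.truth


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
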