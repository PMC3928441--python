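import dataclasses

import numpy as np
import pandas as pd
import pytest

from refstab import (
    SimulationConfig,
    average_replicates,
    build_expression_matrix,
    fit_standard_curves,
    simulate_experiment,
    simulate_standard_curves,
)


def noise_free_config(**overrides) -> SimulationConfig:
    """Default study design with every noise source silenced."""
    cfg = SimulationConfig(**overrides)
    genes = tuple(
        dataclasses.replace(g, residual_sd_log2=0.0, tech_rep_sd_ct=0.0)
        for g in cfg.genes
    )
    return cfg.with_overrides(genes=genes, loading_sd_log2=0.0)


def quantify_chain(cfg: SimulationConfig, seed: int):
    """simulate -> average replicates -> fit curves -> expression matrix."""
    ct, truth = simulate_experiment(cfg, seed=seed)
    dilution = simulate_standard_curves(cfg, seed=seed)
    curves = fit_standard_curves(dilution)
    matrix = build_expression_matrix(average_replicates(ct), curves)
    return matrix, truth


@pytest.fixture
def default_config() -> SimulationConfig:
    return SimulationConfig(seed=0)


@pytest.fixture
def small_matrix() -> pd.DataFrame:
    """4 genes x 6 samples, positive, reproducible."""
    rng = np.random.default_rng(42)
    data = 2.0 ** rng.normal(0, 0.5, size=(4, 6))
    return pd.DataFrame(
        data,
        index=[f"g{i}" for i in range(4)],
        columns=[f"s{j}" for j in range(6)],
    )
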