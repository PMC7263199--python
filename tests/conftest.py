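import numpy as np
import pytest

from methylmark import simulate


@pytest.fixture(scope="session")
def full_dataset():
    """Canonical study-scale synthetic dataset, shared across test modules."""
    cfg = simulate.SimulationConfig(seed=11)
    annot = simulate.simulate_annotation(cfg.n_probes, cfg.seed,
                                         snp_frac=cfg.snp_frac,
                                         sex_frac=cfg.sex_frac,
                                         n_genes=cfg.n_genes)
    beta, sheet, truth = simulate.simulate_cohorts(cfg, annot)
    counts = simulate.simulate_expression(beta, sheet, annot, truth, cfg)
    return cfg, annot, beta, sheet, counts, truth


@pytest.fixture(scope="session")
def small_config():
    """Reduced configuration for fast end-to-end runs."""
    return simulate.SimulationConfig(
        seed=5, n_probes=3000,
        cohorts=[("BRCA", 30, 30), ("CANC1", 20, 12), ("CANC2", 20, 12)],
        n_healthy=15, n_cimp_extra=60, n_genes=150, n_de_genes=20,
        background_hyper_frac=0.01)


@pytest.fixture
def rng():
    return np.random.default_rng(42)
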