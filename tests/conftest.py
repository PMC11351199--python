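import pytest

from synviab import SimulationConfig, simulate_dataset, simulate_null_dataset


@pytest.fixture(scope="session")
def default_sim():
    """Default noisy cohort (90 cases vs 140 controls, 20 planted bands)."""
    return simulate_dataset(SimulationConfig(seed=11))


@pytest.fixture(scope="session")
def noiseless_sim():
    """Deterministic-expression cohort: planted truth is exactly recoverable."""
    cfg = SimulationConfig(seed=5, expr_noise_sd=0.0, bf_noise_sd=0.0)
    return simulate_dataset(cfg)


@pytest.fixture(scope="session")
def null_sim():
    """No-signal cohort at baseline deletion probability 0.2."""
    cfg = SimulationConfig(seed=23, baseline_del_prob=0.2)
    return simulate_null_dataset(cfg)


@pytest.fixture(scope="session")
def small_sim():
    """Tiny cohort for fast structural tests."""
    cfg = SimulationConfig(seed=3, n_case=12, n_control=16, n_cytobands=20,
                           n_genes=60, n_enriched_cytobands=4,
                           n_switch_genes=6, n_mutated_genes=10,
                           bands_per_chrom=10)
    return simulate_dataset(cfg)
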