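import pytest

from tandemkit.simulate import SimulationConfig, run_pipeline


@pytest.fixture(scope="session")
def zero_error_run(tmp_path_factory):
    """Zero-noise simulation: 50 loci, coverage 30 — exact recovery baseline."""
    cfg = SimulationConfig(
        seed=11, n_loci=50, coverage=30, p_del=0.0, p_ins=0.0, p_sub=0.0
    )
    wd = tmp_path_factory.mktemp("zero_error")
    loci, truth, allele_table, locus_table = run_pipeline(cfg, str(wd))
    return cfg, loci, truth, allele_table, locus_table


@pytest.fixture(scope="session")
def noisy_run(tmp_path_factory):
    """Deletion-skew simulation (p_del=0.3, p_ins=0.05), 200 loci, 30x."""
    cfg = SimulationConfig(seed=5, n_loci=200, coverage=30)
    wd = tmp_path_factory.mktemp("noisy30")
    loci, truth, allele_table, locus_table = run_pipeline(cfg, str(wd))
    return cfg, loci, truth, allele_table, locus_table


@pytest.fixture(scope="session")
def noisy_run_60(tmp_path_factory):
    """Same conditions at doubled coverage, for the coverage-trend check."""
    cfg = SimulationConfig(seed=5, n_loci=200, coverage=60)
    wd = tmp_path_factory.mktemp("noisy60")
    loci, truth, allele_table, locus_table = run_pipeline(cfg, str(wd))
    return cfg, loci, truth, allele_table, locus_table
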