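"""Shared fixtures: one moderate synthetic study reused across test modules."""

import pandas as pd
import pytest

import methdyn as md


@pytest.fixture(scope="session")
def sim_config() -> md.SimConfig:
    """A small 3x3 study with planted DMRs and DEGs."""
    return md.SimConfig(
        seed=42,
        n_chroms=2,
        chrom_length=150_000,
        n_genes=40,
        n_dmrs=12,
        n_degs=30,
        control_sites=2_000,
    )


@pytest.fixture(scope="session")
def catalog(sim_config) -> md.FeatureCatalog:
    return md.build_toy_annotation(sim_config)


@pytest.fixture(scope="session")
def methylome(sim_config, catalog):
    """(reports_by_sample, truth) for the shared study."""
    return md.simulate_methylome(sim_config, catalog)


@pytest.fixture(scope="session")
def expression(sim_config, catalog, methylome):
    _reports, meth_truth = methylome
    return md.simulate_expression(sim_config, catalog, meth_truth)


@pytest.fixture(scope="session")
def calls_by_sample(methylome) -> dict[str, pd.DataFrame]:
    reports, _ = methylome
    return {s: md.call_true_methylated(r) for s, r in reports.items()}


@pytest.fixture(scope="session")
def sample_groups(sim_config) -> dict[str, str]:
    return dict(sim_config.samples)
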