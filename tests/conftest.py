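import pytest

from lncepi.simulate import GroundTruthManifest, SimulationConfig, generate_dataset


@pytest.fixture(scope="session")
def sim_config() -> SimulationConfig:
    """Small synthetic dataset used across the unit tests."""
    return SimulationConfig(
        seed=7,
        n_lincRNA=40,
        n_NAT=20,
        n_incRNA=12,
        n_putative_mRNA=15,
        n_genes=30,
        n_chroms=2,
        chrom_length=600_000,
    )


@pytest.fixture(scope="session")
def dataset(tmp_path_factory, sim_config):
    """(path, manifest) of the session-wide synthetic dataset."""
    outdir = tmp_path_factory.mktemp("simdata")
    manifest = generate_dataset(sim_config, outdir)
    return outdir, manifest
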