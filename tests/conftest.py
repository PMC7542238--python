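import numpy as np
import pytest

from snproi import SimulationConfig, simulate_dataset


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def small_dataset():
    """200 samples x 60 SNPs x 4 ROIs, 6 LD blocks, linear link."""
    cfg = SimulationConfig(n_samples=200, p_snps=60, q_rois=4, n_blocks=6,
                           n_active_groups=2, seed=7)
    return simulate_dataset(cfg)


@pytest.fixture
def genotype_file(tmp_path):
    path = tmp_path / "geno.tsv"
    path.write_text(
        "sample\tsnp1\tsnp2\n"
        "s1\t0\t2\n"
        "s2\t1\t0\n"
        "s3\t2\t1\n"
    )
    return str(path)


@pytest.fixture
def phenotype_file(tmp_path):
    path = tmp_path / "pheno.tsv"
    path.write_text(
        "sample\troiA\troiB\n"
        "s1\t1.5\t-0.25\n"
        "s2\t2.75\t3.125\n"
    )
    return str(path)
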