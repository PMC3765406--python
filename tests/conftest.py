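import numpy as np
import pytest

from pafcontrast import GenotypeTable, SimConfig, SnpRecord, generate_dataset


@pytest.fixture(scope="session")
def small_dataset():
    """A modest simulated study shared by read-only tests."""
    config = SimConfig(
        n_snps=1200, n_samples_study=120, n_genes=60, n_groups=8, seed=42,
        enriched_groups=(("group01", 2.0),),
    )
    return config, generate_dataset(config)


@pytest.fixture
def toy_records():
    return [
        SnpRecord("rs1", "1", 100, "A", "G", "+", "A"),
        SnpRecord("rs2", "2", 200, "C", "T", "+", "T"),
    ]


@pytest.fixture
def toy_genotypes(toy_records):
    codes = np.array([[0, 1], [2, -1]], dtype=np.int8)
    return GenotypeTable(["s1", "s2"], ["rs1", "rs2"], codes)
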