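import numpy as np
import pandas as pd
import pytest

from cssig import GenotypePanel, SimulationConfig, simulate_two_pop_panel


def make_panel(haplotypes, positions=None, chrom="1", cohorts=None, phased=True):
    """Small panel from an explicit haplotype matrix (rows = haplotypes)."""
    hap = np.asarray(haplotypes, dtype=np.int8)
    n_hap, n_snps = hap.shape
    assert n_hap % 2 == 0
    n_ind = n_hap // 2
    if positions is None:
        positions = (np.arange(n_snps) + 1) * 1000
    snps = pd.DataFrame(
        {
            "id": [f"s{j}" for j in range(n_snps)],
            "chrom": chrom,
            "pos_bp": np.asarray(positions, dtype=int),
            "ref": "A",
            "alt": "G",
        }
    )
    if cohorts is None:
        cohorts = ["pop1"] * n_ind
    individuals = pd.DataFrame(
        {"id": [f"i{k}" for k in range(n_ind)], "sex": (["M", "F"] * n_ind)[:n_ind], "cohort": cohorts}
    )
    return GenotypePanel(snps, hap, individuals, phased=phased)


@pytest.fixture(scope="session")
def null_panel():
    """Two-cohort Balding-Nichols panel, no sweep (session cache: read-only)."""
    return simulate_two_pop_panel(SimulationConfig(n_snps=600, seed=17))


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
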