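import numpy as np
import pandas as pd
import pytest

from sweepscan import GenotypeDataset, SimConfig
from sweepscan.datatypes import SITE_COLUMNS


def make_dataset(genotypes, positions=None, chrom="chr1", populations=None):
    """Hand-build a GenotypeDataset from a (sites x samples) array."""
    g = np.asarray(genotypes, dtype=np.int8)
    n_sites, n_samples = g.shape
    if positions is None:
        positions = np.arange(1, n_sites + 1) * 100
    if populations is None:
        populations = ["pop1"] * n_samples
    sites = pd.DataFrame(
        {
            "chrom": chrom if isinstance(chrom, str) else list(chrom),
            "pos": positions,
            "ref": "A",
            "alt": "G",
            "depth": 30.0,
            "mapq": 60.0,
        }
    )[SITE_COLUMNS]
    samples = [f"s{i}" for i in range(n_samples)]
    return GenotypeDataset(samples, np.array(populations, dtype=object), sites, g)


@pytest.fixture
def small_sim_config():
    """Small two-population config used by several integration tests."""
    return SimConfig(
        n_pop1=30,
        n_pop2=20,
        n_chrom=2,
        chrom_length_bp=1_000_000,
        n_sites=300,
        fst_param=0.2,
        sweep_alpha=None,
        sweep_position_bp=None,
        missing_rate=0.05,
        n_causal=2,
        h2_snp=0.3,
        h2_poly=0.2,
        seed=42,
    )


@pytest.fixture
def bn_dataset():
    """Balding-Nichols dataset at F=0.2, no sweep, no missingness."""
    from sweepscan import simulate_divergent_genotypes

    cfg = SimConfig(
        n_pop1=40,
        n_pop2=40,
        n_chrom=1,
        chrom_length_bp=2_000_000,
        n_sites=1000,
        fst_param=0.2,
        sweep_alpha=None,
        sweep_position_bp=None,
        missing_rate=0.0,
        seed=7,
    )
    return simulate_divergent_genotypes(cfg)
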