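import sys
from pathlib import Path

import pytest

sys.path.insert(0, str(Path(__file__).parent))

import genedomains as gd  # noqa: E402


@pytest.fixture(scope="session")
def small_sim():
    """One modest simulated chromosome with planted single-gene domains."""
    cfg = gd.SimulationConfig(
        chrom_length=400_000,
        resolution=250,
        n_genes=40,
        frac_single_domains=0.3,
        depth_c=100.0,
        enrichment=3.0,
        seed=11,
    )
    genes, truth = gd.simulate_annotation(cfg)
    m = gd.balance_matrix(gd.simulate_contacts(genes, truth, cfg))
    e = gd.expected_profile(m)
    return cfg, genes, truth, m, e
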