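import numpy as np
import pandas as pd
import pytest

import pleiokit as pk


@pytest.fixture(scope="session")
def small_cfg():
    return pk.SimulationConfig(m_snps=400, n1=20000, n2=20000, block_size=20,
                               block_rho=0.8, pi_shared=0.05,
                               sign_concordance=0.7, h2_a=0.5, h2_b=0.5,
                               seed=101)


@pytest.fixture(scope="session")
def small_panel(small_cfg):
    return pk.simulate_ld_genotypes(small_cfg, n_samples=500)


@pytest.fixture(scope="session")
def small_pair(small_cfg, small_panel):
    ss1, ss2, truth = pk.simulate_sumstats_pair(small_cfg, small_panel)
    return ss1, ss2, truth


def toy_sumstats(p, chrom=None, pos=None, z=None):
    """Build a SummaryStats table from a vector of p-values."""
    p = np.asarray(p, dtype=float)
    m = p.size
    chrom = np.ones(m, dtype=int) if chrom is None else np.asarray(chrom)
    pos = (np.arange(m) + 1) * 10_000_000 if pos is None else np.asarray(pos)
    if z is None:
        from scipy import stats
        z = stats.norm.isf(p / 2.0)
    return pk.SummaryStats(pd.DataFrame({
        "snp": [f"v{i}" for i in range(m)],
        "chrom": chrom, "pos": pos,
        "a1": "A", "a2": "G",
        "z": z, "p": p, "n": 10_000,
    }))
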