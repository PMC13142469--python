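import numpy as np
import pandas as pd
import pytest

import laibench as lb
import laibench.experiments as ex


@pytest.fixture
def tiny_panel():
    """Five SNPs on one chromosome, 1 cM apart."""
    return lb.SitePanel(
        pd.DataFrame(
            {
                "chrom": "1",
                "pos": [1_000_000, 2_000_000, 3_000_000, 4_000_000, 5_000_000],
                "cm": [0.0, 1.0, 2.0, 3.0, 4.0],
                "ref": "A",
                "alt": "G",
                "maf": 0.3,
                "info": 1.0,
            }
        )
    )


@pytest.fixture(scope="session")
def default_cohort():
    """One small cohort at the generator's default conditions."""
    return lb.simulate_cohort(lb.SimulationConfig(n_admixed=15, seed=0))


@pytest.fixture(scope="session")
def imbalance_table():
    """Shared source-imbalance experiment (8 seeds), used by several checks."""
    return ex.source_imbalance_experiment(list(range(8)))


def make_calls(labels, haplotypes=None, posterior=None, method="test"):
    labels = np.asarray(labels, dtype=np.int8)
    if haplotypes is None:
        haplotypes = [f"i{k // 2}.{k % 2}" for k in range(labels.shape[0])]
    return lb.AncestryCalls(haplotypes, labels, posterior, method)
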