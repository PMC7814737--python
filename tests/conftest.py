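import numpy as np
import pandas as pd
import pytest

from promact.features import PromoterFeaturizer
from promact.simulate import SimConfig, simulate_cohort


@pytest.fixture(scope="session")
def small_cohort():
    """Two 300-promoter samples sharing half their states."""
    cfg = SimConfig(n_promoters=300, seed=42)
    return simulate_cohort(cfg, 2, shared_fraction=0.5)


@pytest.fixture(scope="session")
def small_sample(small_cohort):
    return small_cohort[0]


@pytest.fixture(scope="session")
def small_tensor(small_sample):
    feat = PromoterFeaturizer(small_sample.catalog).fit()
    return feat.transform(small_sample.methylation, sample_id=small_sample.sample_id)


def make_tss_table(rows):
    """rows: (transcript_id, gene_id, gene_type, chrom, strand, tss)"""
    return pd.DataFrame(
        rows, columns=["transcript_id", "gene_id", "gene_type", "chrom", "strand", "tss"]
    )


@pytest.fixture
def rng():
    return np.random.default_rng(0)
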