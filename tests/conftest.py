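import numpy as np
import pytest

from tcrdyn.params import TcrParams
from tcrdyn.synthetic import (
    SyntheticGenomeConfig,
    SyntheticTumorConfig,
    generate_cohort,
    generate_genome,
)

TUMOR_FIT = TcrParams(pd=0.42, pr=0.66, pv=0.8, m=1.59)


@pytest.fixture(scope="session")
def small_genome():
    cfg = SyntheticGenomeConfig(
        n_chroms=2, chrom_length=1_500_000, n_genes=40,
        gene_length_median=30_000, max_gene_length=150_000,
    )
    return generate_genome(cfg, rng=11)


@pytest.fixture(scope="session")
def small_cohort(small_genome):
    """30 tumors at the headline fitted parameters on the small genome."""
    cfg = SyntheticTumorConfig(params=TUMOR_FIT, n_tumors=30)
    muts, phases, truths, manifest = generate_cohort(small_genome, cfg, rng=5)
    return muts, phases, truths, manifest


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
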