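import numpy as np
import pandas as pd
import pytest

from psrp.matrix import ScoreMatrix
from psrp.qpcr import CtTable, flag_unexpressed
from psrp.simulate import SimConfig, generate_cohort


@pytest.fixture(scope="session")
def default_cohort():
    """A default-settings 18-patient matched cohort (shared, read-only)."""
    return generate_cohort(SimConfig(seed=11))


@pytest.fixture
def noiseless_config():
    """Factory for configs with every noise source and FFPE shift at zero.

    Latent means and Ct intercepts are placed so no gene approaches the
    detection threshold: censoring would otherwise make the two
    platforms see different sample subsets per gene.
    """

    def make(**overrides):
        base = dict(
            n_patients=10,
            latent_mean_range=(6.0, 12.0),
            qpcr_intercept_range=(34.0, 36.0),
            latent_sd=1.0,
            array_noise_sd=0.0,
            qpcr_noise_sd=0.0,
            ffpe_shift_mean=0.0,
            ffpe_shift_sd=0.0,
            ffpe_extra_noise_sd=0.0,
            hk_stability_sd=0.0,
            seed=21,
        )
        base.update(overrides)
        return SimConfig(**base)

    return make


@pytest.fixture
def random_ct_table():
    """Factory for randomized single-sample Ct tables (threshold applied)."""

    def make(rng, n_genes=8, hk=("GAPDH", "HPRT1", "GUSB"), sample_id="S1"):
        genes = [f"G{i:02d}" for i in range(n_genes)]
        cts = dict(zip(genes, rng.uniform(18.0, 36.0, n_genes)))
        cts.update(dict(zip(hk, rng.uniform(18.0, 22.0, len(hk)))))
        return flag_unexpressed(CtTable(sample_id=sample_id, measurements=cts))

    return make


@pytest.fixture
def small_scores():
    """Tiny qPCR-tagged score matrix with one missing entry."""
    values = pd.DataFrame(
        {
            "s1": [1.0, 2.0, -0.5],
            "s2": [2.0, np.nan, 0.5],
            "s3": [3.0, 4.0, 1.5],
        },
        index=pd.Index(["g1", "g2", "g3"], name="gene_id"),
    )
    return ScoreMatrix(values, platform="qpcr", housekeeping=("GAPDH",))
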