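import numpy as np
import pytest

from admixscan.sim import PhenoModel, RelatednessSpec, SimConfig, simulate_cohort


@pytest.fixture(scope="session")
def related_cohort():
    """Small cohort with embedded parent-offspring and duplicate pairs."""
    config = SimConfig(
        n_samples=240,
        n_variants_per_chrom=500,
        chrom_lengths_cm=(150.0, 150.0, 150.0, 150.0),
        relatedness=RelatednessSpec(n_parent_offspring=4, n_duplicate=2),
        seed=42,
    )
    return simulate_cohort(config)


@pytest.fixture(scope="session")
def causal_cohort():
    """Cohort with a strong protective NAM ancestry effect at one block."""
    config = SimConfig(
        n_samples=800,
        n_variants_per_chrom=30,
        chrom_lengths_cm=tuple([150.0] * 6),
        pheno=PhenoModel(ancestry_logor=float(np.log(0.4)), causal_block=30),
        seed=7,
    )
    return simulate_cohort(config)
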