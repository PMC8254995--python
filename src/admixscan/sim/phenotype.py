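"""Case-control phenotype and covariate simulation.

Disease status is drawn prospectively from a logistic model whose linear
predictor combines centered covariates (age, sex, APOE e2/e4 dosages), an
optional ancestry-dosage effect at a designated causal block, and an
optional allelic effect at a designated causal SNP.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.special import expit
from scipy.stats import truncnorm

from admixscan.sim.config import SimConfig
from admixscan.sim.tracts import LocalAncestryMatrix


def draw_covariates(config: SimConfig, n: int, rng: np.random.Generator) -> pd.DataFrame:
    """Age (truncated normal on [35, 100]), sex (1=female), APOE dosages."""
    a, b = (35.0 - config.age_mean) / config.age_sd, (100.0 - config.age_mean) / config.age_sd
    age = truncnorm.rvs(
        a, b, loc=config.age_mean, scale=config.age_sd, size=n, random_state=rng
    )
    sex = (rng.random(n) < config.female_prob).astype(np.int8)
    e2 = rng.binomial(2, config.e2_freq, size=n).astype(np.int8)
    e4 = rng.binomial(2, config.e4_freq, size=n).astype(np.int8)
    return pd.DataFrame({"age": age, "sex": sex, "apoe_e2": e2, "apoe_e4": e4})


def simulate_phenotype(
    tracts: LocalAncestryMatrix,
    genotypes: np.ndarray | None,
    config: SimConfig,
    rng: np.random.Generator | int | None = None,
    covariates: pd.DataFrame | None = None,
) -> tuple[np.ndarray, pd.DataFrame]:
    """Binary disease status plus the covariate table used to generate it."""
    rng = np.random.default_rng(rng)
    n = tracts.n_samples
    pm = config.pheno
    if covariates is None:
        covariates = draw_covariates(config, n, rng)
    eta = np.full(n, pm.intercept, dtype=float)
    eta += pm.beta_age * (covariates["age"].to_numpy() - config.age_mean)
    eta += pm.beta_sex * (covariates["sex"].to_numpy() - config.female_prob)
    eta += pm.beta_e2 * (covariates["apoe_e2"].to_numpy() - 2 * config.e2_freq)
    eta += pm.beta_e4 * (covariates["apoe_e4"].to_numpy() - 2 * config.e4_freq)
    if pm.ancestry_logor != 0.0:
        if pm.causal_block is None or not (0 <= pm.causal_block < tracts.n_blocks):
            raise ValueError("causal_block must name an existing block")
        dose = tracts.dosages[:, pm.causal_block, pm.causal_ancestry].astype(float)
        eta += pm.ancestry_logor * dose
    if pm.allelic_logor != 0.0:
        if genotypes is None or pm.causal_snp is None or not (
            0 <= pm.causal_snp < genotypes.shape[1]
        ):
            raise ValueError("causal_snp must name an existing variant")
        eta += pm.allelic_logor * genotypes[:, pm.causal_snp].astype(float)
    phenotype = (rng.random(n) < expit(eta)).astype(np.int8)
    return phenotype, covariates
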