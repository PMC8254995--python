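"""The Cohort container and the end-to-end cohort simulator."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from admixscan.sim.config import GeneticMap, SimConfig
from admixscan.sim.genotypes import simulate_genotypes
from admixscan.sim.phenotype import simulate_phenotype
from admixscan.sim.relatives import add_relatedness
from admixscan.sim.tracts import LocalAncestryMatrix, perturb_local_ancestry, simulate_tracts

MISSING = -1  # missing-genotype code


@dataclass
class Cohort:
    """Genotypes, local ancestry, phenotype and covariates for one cohort.

    ``genotypes`` is samples x variants with values {0, 1, 2, -1(missing)};
    ``tracts`` holds the *observed* local ancestry (possibly noise-perturbed);
    ``truth`` carries everything the generator knows: the SimConfig, the true
    tracts, haplotype alleles, embedded kinship pairs, and causal ids.
    """

    sample_ids: list[str]
    genotypes: np.ndarray
    variants: pd.DataFrame
    tracts: LocalAncestryMatrix
    phenotype: np.ndarray
    covariates: pd.DataFrame
    gmap: GeneticMap
    truth: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        n = len(self.sample_ids)
        if self.genotypes.shape[0] != n or len(self.phenotype) != n:
            raise ValueError("sample dimension mismatch")
        if self.genotypes.shape[1] != len(self.variants):
            raise ValueError("variant dimension mismatch")
        if not np.isin(self.phenotype, [0, 1]).all():
            raise ValueError("phenotype must be binary")
        for col in ("apoe_e2", "apoe_e4"):
            if col in self.covariates and not np.isin(self.covariates[col], [0, 1, 2]).all():
                raise ValueError(f"{col} dosages must lie in {{0,1,2}}")

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @property
    def n_variants(self) -> int:
        return len(self.variants)

    def summary(self) -> pd.DataFrame:
        """Affected/unaffected/total table: N, %female, mean(sd) age, e2/e4 freq."""
        rows = []
        groups = [
            ("affected", self.phenotype == 1),
            ("unaffected", self.phenotype == 0),
            ("total", np.ones(self.n_samples, dtype=bool)),
        ]
        for name, sel in groups:
            cov = self.covariates[sel]
            rows.append(
                {
                    "sample": name,
                    "n": int(sel.sum()),
                    "pct_female": 100 * cov["sex"].mean(),
                    "age_mean": cov["age"].mean(),
                    "age_sd": cov["age"].std(),
                    "e2_freq_pct": 100 * cov["apoe_e2"].mean() / 2,
                    "e4_freq_pct": 100 * cov["apoe_e4"].mean() / 2,
                }
            )
        return pd.DataFrame(rows)


def simulate_cohort(config: SimConfig) -> Cohort:
    """Simulate a full cohort: tracts -> genotypes -> relatives -> phenotype -> noise.

    The phenotype is generated from the *true* local ancestry; if
    ``la_noise_rate`` > 0 the observed tracts handed to downstream analyses
    are a perturbed copy, with the truth retained in ``cohort.truth``.
    """
    ss = np.random.SeedSequence(config.seed)
    r_tracts, r_geno, r_rel, r_pheno, r_noise = [
        np.random.default_rng(s) for s in ss.spawn(5)
    ]
    tracts = simulate_tracts(config, rng=r_tracts)
    genotypes, variants, hap_alleles = simulate_genotypes(tracts, config, rng=r_geno)
    cohort = Cohort(
        sample_ids=list(tracts.sample_ids),
        genotypes=genotypes,
        variants=variants,
        tracts=tracts,
        phenotype=np.zeros(tracts.n_samples, dtype=np.int8),
        covariates=pd.DataFrame(index=range(tracts.n_samples)),
        gmap=config.genetic_map(),
        truth={
            "config": config,
            "true_tracts": tracts,
            "hap_alleles": hap_alleles,
            "kinship_pairs": [],
            "sim_stats": tracts.sim_stats,
        },
    )
    if config.relatedness.n_pairs:
        cohort = add_relatedness(cohort, config.relatedness, rng=r_rel)
    phenotype, covariates = simulate_phenotype(tracts, cohort.genotypes, config, rng=r_pheno)
    cohort.phenotype = phenotype
    cohort.covariates = covariates
    if config.la_noise_rate > 0:
        cohort.tracts = perturb_local_ancestry(tracts, config.la_noise_rate, rng=r_noise)
    cohort.truth["causal_block"] = config.pheno.causal_block
    cohort.truth["causal_snp"] = config.pheno.causal_snp
    return cohort
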