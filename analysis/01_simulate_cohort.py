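"""Simulate the reference admixed case-control cohort used by all later steps.

Generates a three-way admixed cohort (AFR/EUR/NAM = 0.33/0.58/0.09, g = 10,
30-Morgan genome observed at ~200 local-ancestry windows) with a protective
Native American ancestry effect (OR 0.58) at one designated block, a handful
of embedded relative pairs, and writes VCF / local-ancestry / phenotype /
truth files under results/cohort/.
"""

import json
from pathlib import Path

import numpy as np

from admixscan import io as aio
from admixscan.sim import PhenoModel, RelatednessSpec, SimConfig, simulate_cohort

SEED = 20240901
OUT = Path(__file__).resolve().parents[1] / "results" / "cohort"


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    config = SimConfig(
        n_samples=1500,
        n_variants_per_chrom=25,
        pheno=PhenoModel(
            ancestry_logor=float(np.log(0.58)), causal_block=100, intercept=-0.17
        ),
        relatedness=RelatednessSpec(n_parent_offspring=10, n_duplicate=2),
        seed=SEED,
    )
    cohort = simulate_cohort(config)
    aio.write_vcf(OUT / "genotypes.vcf", cohort.genotypes, cohort.variants,
                  cohort.sample_ids, hap_alleles=cohort.truth["hap_alleles"])
    aio.write_la_dosages(OUT / "local_ancestry_dosages.tsv", cohort.tracts)
    aio.write_phenotype(OUT / "phenotype.tsv", cohort.sample_ids, cohort.phenotype,
                        cohort.covariates)
    aio.write_json(
        OUT / "truth.json",
        {
            "seed": SEED,
            "causal_block": cohort.truth["causal_block"],
            "true_or_nam": 0.58,
            "kinship_pairs": cohort.truth["kinship_pairs"],
        },
    )
    summary = cohort.summary()
    summary.to_csv(OUT / "sample_summary.tsv", sep="\t", index=False)
    print(f"cohort: {cohort.n_samples} samples, {cohort.n_variants} variants, "
          f"{cohort.tracts.n_blocks} local-ancestry blocks")
    print(f"case fraction: {cohort.phenotype.mean():.3f}")
    print(summary.round(2).to_string(index=False))
    print(f"written to {OUT}")


if __name__ == "__main__":
    main()
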