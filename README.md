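# admixscan

Admixture mapping of case-control traits in three-way admixed cohorts.

Recently admixed populations — here modeled on Caribbean Hispanic cohorts
with African, European and Native American ancestry — carry long stretches
of chromosome inherited from each ancestral population.  Admixture mapping
tests whether the *ancestral origin* of a genomic segment (its local
ancestry), rather than the alleles it carries, associates with disease.
Because admixture LD extends over tens of megabases, a genome scan involves
only a few hundred effectively independent tests, giving this design power
where a conventional GWAS at the same sample size has none.

`admixscan` implements the full analysis as a tested Python library with
numbered analysis drivers:

- **Simulation** (`admixscan.sim`) — three-way admixed cohorts with known
  truth: Poisson ancestry tracts (rate *g* per Morgan), Balding–Nichols
  ancestral allele frequencies, logistic case-control phenotypes with
  age/sex/APOE covariates, embedded relatives, local-ancestry noise.
- **QC** (`admixscan.qc`) — missingness filters, heterozygosity-outlier
  detection (F > 0.12 **and** het < 0.28), cM-weighted global ancestry.
- **Relatedness** (`admixscan.relatedness`) — recursive ancestry-robust
  GRM: KING-robust kinship → unrelated/related partition → PCA with
  projection → PC-adjusted kinship, repeated.
- **Scan** (`admixscan.mixedmodel`, `admixscan.scan`) — logistic mixed
  model (PQL + AI-REML) with the GRM as random effect; joint 2-df and
  single-ancestry score tests per admixture-LD block; SNP score tests;
  conditional models; odds ratios from Wald refits; LD (r², D′) with EM
  haplotype frequencies (`admixscan.ld`).
- **Multiple testing** (`admixscan.multtest`) — per-ancestry effective
  test counts from autoregressive models on local-ancestry dosages,
  combined as the sum of the two largest; Bonferroni thresholds; simpleM
  regional counts for SNP association.
- **Colocalization** (`admixscan.coloc`) — Wakefield approximate Bayes
  factors and posterior probabilities PP0–PP4 against eQTL summary
  statistics.

The core scan statistic: with null model
logit P(yᵢ=1) = xᵢ′β + bᵢ, b ~ N(0, σ²_g Φ), a block with ancestry dosages
S (samples × 2 after dropping the reference ancestry) is tested by
T = U′V⁻¹U with U = S′PỸ, V = S′PS, where P is the REML projection of the
converged fit — no refit per block.  The scan threshold is α divided by
the effective number of tests; with per-ancestry counts (251.1, 210.3,
281.2) the sum-of-two-largest rule gives 532.3 and a threshold of
9.39E−05 at α = 0.05.

## Worked example

```python
import numpy as np
from admixscan.sim import SimConfig, PhenoModel, simulate_cohort
from admixscan.relatedness import recursive_grm
from admixscan.qc import global_ancestry
from admixscan.mixedmodel import build_design, fit_null
from admixscan.multtest import effective_tests_for_scan
from admixscan.scan import admixture_scan

cfg = SimConfig(n_samples=1500, n_variants_per_chrom=25,
                pheno=PhenoModel(ancestry_logor=np.log(0.58), causal_block=100),
                seed=20240901)
cohort = simulate_cohort(cfg)
grm, pcs = recursive_grm(cohort.genotypes, sample_ids=cohort.sample_ids)
X, names = build_design(cohort.covariates, global_ancestry(cohort.tracts))
null = fit_null(cohort.phenotype, X, grm.values)
eff = effective_tests_for_scan(cohort.tracts)
res = admixture_scan(cohort.tracts, null, grm.values, significant=eff.threshold)
top = res.loc[res["p"].idxmin()]
print(top["chrom"], top["driving_ancestry"], top["odds_ratio"], top["p"])
```

Running the equivalent analysis chain (`python analysis/01_simulate_cohort.py`
… `04_admixture_scan.py`) prints, for the cohort above:

```
effective tests AFR/EUR/NAM: 155.5/171.1/148.2; combined 326.6; threshold 0.000153
top block: chr11:1-15000001  joint p = 0.000924  driving ancestry NAM  OR = 0.59 (0.45-0.78)
```

The scan's top block is exactly the simulated causal block (index 100 =
first window of chr11), the driving ancestry is Native American, and the
Wald refit recovers the configured protective odds ratio 0.58 within its
CI.  At n = 1500 the block is suggestive rather than genome-wide
significant — the power analysis in the test suite shows the causal block
attains the scan minimum in nearly all replicates at n = 2500.  Step 03
prints the relatedness check: embedded parent-offspring pairs (truth
kinship 0.25) and duplicates (0.5) are recovered by the PC-adjusted GRM
with mean absolute error 0.018.  Steps 05–06 demonstrate conditional
admixture mapping (conditioning on the causal SNP removes the block
signal) and colocalization (PP4 ≈ 1 for a shared causal variant, PP3 ≈ 1
for distinct ones).

A CLI wraps the same stages:

```bash
admixscan simulate --seed 3 --out run/
admixscan grm --vcf run/genotypes.vcf --out run/grm/
admixscan ntests --la run/local_ancestry.tsv --alpha 0.05
admixscan coloc --a scan.tsv --b eqtl.tsv --p12 1e-5
```

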