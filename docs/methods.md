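# Methods

This note documents the models, estimators and numerical choices behind
`admixscan`, and what the synthetic cohorts it validates against do and do
not capture.

## The scientific setting

Admixture mapping asks whether the *ancestral origin* of a haplotype — not
its alleles — associates with a trait, exploiting the long-range ancestry
correlation ("admixture LD") created by recent three-way admixture in
populations such as Caribbean Hispanics (African, European and Native
American ancestry; AFR=0, EUR=1, NAM=2 throughout this package).  The
workflow is: simulate or load an admixed case-control cohort; clean it;
estimate an ancestry-robust genetic relatedness matrix (GRM); fit a
logistic mixed-model null; score-test local ancestry per admixture-LD
block (jointly and per ancestry); correct for the effective number of
tests; then interrogate significant regions with SNP association,
conditional models, LD and colocalization.

## Synthetic cohorts

**Tract model.** Hybrid-isolation Markov approximation: along each
haplotype, ancestry switch points follow a Poisson process with rate `g`
per Morgan (`g` = generations since admixture, default 10 — a choice, not
an inference from data) and each segment's ancestry is drawn independently
from the global proportions (default 0.33/0.58/0.09 AFR/EUR/NAM).  This
reproduces the first-order admixture-LD decay but ignores drift in
ancestry proportions, multi-wave admixture, assortative mating, and
correlations between neighbouring segments.

**Observation grid.** Ancestry is *recorded* on a marker-window grid
(`window_cm`, default 15 cM over a 20 x 150 cM genome, i.e. ~200 windows),
as windowed local-ancestry inference tools emit; the continuous switch
process is simulated exactly and retained for validation (switch counts
are Poisson; pooled mean tract length is L/(gL+1) Morgans per chromosome).
Block intervals are the union of observed switch points: adjacent windows
in which no haplotype switches are merged.  The grid bounds the resolution
of block boundaries; with thousands of samples essentially every window
boundary is a block boundary.

**Genotypes.** Alleles are drawn Bernoulli given the *haplotype-level*
ancestry at the variant, with per-population frequencies from a
Balding-Nichols model (shared ancestral frequency, per-population F,
default 0.1, clipped to (0.01, 0.99)).  There is no within-population
allelic LD — variants are independent given ancestry — so allelic
fine-mapping behaviour on real data is only partially represented.

**Phenotype.** Prospective logistic model: intercept (default logit of a
45.8% case fraction) plus centered covariates — age ~ N(73.6, 9.0)
truncated to [35, 100], sex Bernoulli(0.661), APOE e2/e4 dosages
Binomial(2, 0.056/0.207) — plus an optional ancestry-dosage effect at a
designated causal block and an optional allelic effect at a causal SNP.
Covariate defaults are the target cohort's description; effects default
to zero.  Because sampling is prospective (no case-control ascertainment),
logistic coefficients are directly recoverable.

**Relatives.** Parent-offspring pairs replace one haplotype of the
"offspring" with a meiosis product of the parent's two haplotypes
(crossovers at 1 per Morgan); the other haplotype keeps its original
population draw, standing in for an unobserved second parent.  Expected
kinship is exactly 0.25 (0.5 for duplicates), recorded as truth.

**Local-ancestry noise.** Whole haplotype segments are relabeled to a
random other ancestry with probability `la_noise_rate`, modeling
inference error while preserving the dosage-sum invariant.  Phenotypes are
always generated from the *true* ancestry.

## QC

Variants with missingness > 5% are dropped, then samples missing > 5% of
surviving genotypes; the variant-then-sample pass repeats until nothing
changes (removing samples can push a surviving variant past the cut), so
the filter is idempotent.  Heterozygosity outliers require *both* F > 0.12
and heterozygosity rate < 0.28, with F = (observed - expected homozygotes)
/ (m - expected) under Hardy-Weinberg at (by default) sample frequencies;
fixed reference frequencies can be supplied, which also makes F invariant
to sample duplication.  Global ancestry is the cM-length-weighted average
of local dosages/2 — weighting by genetic length makes it invariant to
block re-segmentation.  Duplicates are flagged at kinship >= 0.45.

## Ancestry-robust GRM

The recursive procedure: (1) KING-robust kinship from heterozygote
concordance, phi = (N_het,het - 2 N_opposing_hom)/(N_het_i + N_het_j) —
robust to frequency misspecification, exact 0.5 for duplicates, negative
across diverged ancestries; (2) greedy partition into a mutually-unrelated
set (discard the highest-degree sample until no pair exceeds the
threshold; ties broken toward keeping small sample ids); (3) PCA on the
unrelated set with standardization by unrelated-set frequencies and
projection of related samples onto the same loadings; (4) kinship from
genotype residuals about individual-specific expected dosages predicted by
regressing each variant on the first four PCs (fit on the unrelated set,
predicted for everyone; fitted frequencies clipped to [0.01, 0.99] and
counted); (5) repeat the partition on the adjusted kinship (two iterations
by default; the loop stops early at a fixed point).  The GRM is twice the
final kinship, optionally eigenvalue-clipped to PSD with the clipped mass
reported.

**Partition threshold.** The conventional 3rd-degree cut (kinship 0.025)
assumes dense genotyping.  At the variant counts used here (hundreds to a
few thousand) the sampling SD of pairwise kinship can exceed 0.025, and a
fixed cut would classify most of a cohort as related.  The default is
therefore adaptive: max(0.025, median + z x robust SD of the off-diagonal,
MAD-based), with z chosen so the expected number of false "related" pairs
per matrix is ~0.01.  This keeps parent-offspring (0.25) and duplicates
(0.5) flagged at any panel size but will miss 2nd/3rd-degree relatives on
sparse panels — a documented limitation, not a failure of the procedure on
realistic panels.  Small-n caveat: with few unrelated samples, the 4-PC
regression overfits and shrinks self-kinship by roughly k/n; diagnostics
should be read at n in the hundreds.

## Logistic mixed model and score tests

Null model: logit P(y=1) = X beta + b, b ~ N(0, sigma2_g * Phi), with X =
intercept, global AFR and NAM proportions (EUR omitted; proportions sum to
1), and APOE e2/e4 dosages; age and sex are off by default and available
for sensitivity analyses.  Fitting is penalized quasi-likelihood: the
working response Ytilde = eta + (y - mu)/W is iterated against
Ytilde ~ N(X beta, Sigma), Sigma = W^{-1} + sigma2_g Phi, with sigma2_g
updated by average-information REML (Newton step on the restricted
likelihood; negative steps project to the boundary at 0; the variance
update freezes once its relative change falls below tolerance, after which
iterations only polish beta).  Convergence at relative change < 1e-6 or
100 iterations with a warning.  Fitted probabilities are clipped to
[1e-6, 1-1e-6] with a separation warning.  PQL variance components for
binary traits are conservative (shrunk toward zero, matching glmer-scale
estimates within sampling error in our checks); score tests remain
calibrated, which is what the scan relies on.

Score tests use the converged projection
P = Sigma^{-1} - Sigma^{-1} X (X' Sigma^{-1} X)^{-1} X' Sigma^{-1}:
U = S'P Ytilde, V = S'PS, T = U'V^{-1}U ~ chi-square with df = rank(V)
(eigenvalue-truncated; a fully degenerate test returns p = 1 with df 0).
At sigma2_g = 0 this reduces exactly to the classical logistic score test.
The joint ancestry test scores the AFR and NAM dosage columns (2 df); the
dosage-sum constraint makes the statistic invariant to which ancestry is
dropped, and a test enforces that invariance to 1e-8.  Odds ratios come
from refitting the mixed model with the dosage appended as a fixed effect
(variance component re-estimated, warm-started at the null estimate) and
Wald 95% CIs on the log-odds scale.  Missing dosages are mean-imputed.
Conditional analyses refit the null with the conditioning SNP dosages as
fixed effects, rejecting collinear sets.

Scan conventions: genome-wide admixture significance 5E-05 and suggestive
1E-03; SNP association 5E-08; regional thresholds 0.05/Meff and 1/Meff.
Per block, ORs are refit for the driving (smallest single-ancestry p)
ancestry of blocks passing the suggestive threshold ('auto'; 'all'/'none'
available).  The lead SNP of a block is the smallest association p within
its interval.

## Effective number of tests

Per ancestry, the genome-ordered per-block mean dosage sequence is fit by
an autoregressive model per chromosome (Yule-Walker; order 1 by default).
The per-chromosome effective count is M x gamma0 (1 - sum phi)^2 /
sigma2_e — the variance-to-spectral-density-at-zero ratio, which for AR(1)
is M (1-phi)/(1+phi) — clipped to [1, M] and summed over chromosomes; a
constant sequence counts 1.  Because the three dosages sum to 2, the third
ancestry is redundant, and the combined count is the sum of the two
largest per-ancestry counts; the scan threshold is alpha/combined.  With
the published per-ancestry counts (251.1, 210.3, 281.2) this reproduces
the 9.39E-05 threshold exactly.  For SNP association within a region the
effective count is simpleM-style: the number of leading eigenvalues of the
SNP correlation matrix explaining 99.5% of variance (duplicate columns
collapsed), a documented stand-in for the closed-source Genetic Type I
error calculator.

## Colocalization

Per SNP, the Wakefield approximate Bayes factor
log ABF = 0.5 log(V/(V+W)) + 0.5 z^2 W/(V+W), V = se^2, with effect-prior
SD W = 0.2 for case-control log-odds and 0.15 for quantitative traits.
Five hypotheses over the shared-SNP intersection with priors p1 = p2 =
1e-4, p12 = 1e-5 (reference-implementation defaults; configurable):
PP3's both-traits-different-SNPs term is computed as
exp(S1 + S2) - exp(S12) in log space for stability, and the PPs are
normalized exactly.  Comparing block-level admixture statistics with
SNP-level eQTLs assigns each SNP its containing block's statistic, which
violates the one-causal-variant assumption; a null-leaning outcome (high
PP0) in that configuration is expected rather than anomalous.

## Reference experiments and problem sizes

`admixscan.experiments` pins the validation conditions: (a) OR recovery —
20 seeded cohorts, n = 2500, proportions 0.33/0.58/0.09, g = 10, ~200
blocks, true NAM OR 0.58 at one block; per replicate the full pipeline
runs (recursive GRM from 20 variants/chromosome, mixed-model null,
single-ancestry Wald refit), and the mean estimated OR is compared with
the truth within the mean CI half-width, with >= 18/20 replicate CIs
covering.  GRM eigenvalue clipping is skipped in this driver because the
PQL solver's working-weight diagonal dominates the GRM's small negative
eigenvalues.  (b) Global-ancestry recovery — n = 2000 over a 30-Morgan
genome, cohort mean EUR proportion within 3 SE of 0.58.  The family-wise
error property is checked over 500 small null cohorts (n = 100, 10
chromosomes) at each cohort's derived threshold; the coloc discrimination
properties use split-cohort panels of 800 samples with common causal SNPs.
These sizes were chosen to give stable checks at desk scale; all are
driven by explicit seeds.

## Known limitations

- No within-ancestry allelic LD in the generator; allelic fine-mapping and
  LD-based analyses are exercised on admixture LD only.
- PQL underestimates sigma2_g for binary traits; interpret the variance
  component qualitatively.
- The adaptive partition threshold trades 2nd/3rd-degree sensitivity for
  stability on sparse panels.
- X chromosome, multi-wave admixture and phasing inference are out of
  scope; local ancestry is treated as observed (optionally noisy) truth.
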