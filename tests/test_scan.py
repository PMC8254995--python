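"""Block definition, ancestry score tests, SNP tests, and genome scans."""

import numpy as np
import pandas as pd
import pytest
from scipy.stats import kstest, norm

from admixscan.mixedmodel import build_design, fit_null
from admixscan.qc import global_ancestry
from admixscan.scan import (
    admixture_scan,
    association_scan,
    define_blocks,
    joint_ancestry_test,
    single_ancestry_test,
    snp_score_test,
)
from admixscan.sim import NAM, PhenoModel, SimConfig, simulate_cohort
from admixscan.sim.genotypes import balding_nichols_freqs
from admixscan.sim.tracts import LocalAncestryMatrix


def lam_from_hap(hap_anc, boundaries_mb, chrom="chr1"):
    """LocalAncestryMatrix from explicit haplotype ancestries and boundaries."""
    b = np.asarray(boundaries_mb, dtype=float) * 1e6
    blocks = pd.DataFrame({
        "chrom": chrom,
        "start": np.r_[1, b[:-1].astype(int) + 1][: len(b)],
        "end": b.astype(int) + 1,
        "cm": np.diff(np.r_[0.0, b]) / 1e6,
    })
    n = hap_anc.shape[0]
    return LocalAncestryMatrix(sample_ids=[f"S{i}" for i in range(n)],
                               blocks=blocks, hap_anc=hap_anc.astype(np.int8))


class TestDefineBlocks:
    def test_no_switch_points_one_block_per_chromosome(self):
        hap = np.zeros((3, 4, 2))
        hap[:, :2, :] = 1
        lam = lam_from_hap(hap[:, :2, :], [10, 20])
        assert len(define_blocks(lam)) == 1

    def test_single_switch_two_blocks(self):
        hap = np.zeros((1, 2, 2))
        hap[0, 1, 0] = 1
        lam = lam_from_hap(hap, [10, 20])
        out = define_blocks(lam)
        assert len(out) == 2

    def test_three_sample_toy_matches_hand_enumeration(self):
        # stored windows [0,10) [10,20) [20,30) [30,35) [35,50); switches at
        # 10 (sample 1), 20 (samples 2 and 3), 35 (sample 3); nobody switches
        # at 30 -> merged -> 4 blocks with boundaries {10, 20, 35}
        hap = np.zeros((3, 5, 2))
        hap[0, 1:, 0] = 1  # switch at 10
        hap[1, 2:, 0] = 1  # switch at 20
        hap[2, 2:, 1] = 2  # switch at 20
        hap[2, 4:, 1] = 1  # switch at 35
        lam = lam_from_hap(hap, [10, 20, 30, 35, 50])
        out = define_blocks(lam)
        assert len(out) == 4
        assert out["end"].tolist()[:3] == [10_000_001, 20_000_001, 35_000_001]


@pytest.fixture(scope="module")
def null_fit_300():
    """Null fit on a 300-sample null cohort (no genetic effects)."""
    cfg = SimConfig(n_samples=300, n_variants_per_chrom=40,
                    chrom_lengths_cm=(150.0, 150.0), seed=17)
    cohort = simulate_cohort(cfg)
    props = global_ancestry(cohort.tracts)
    X, names = build_design(cohort.covariates, props)
    return cohort, fit_null(cohort.phenotype, X, grm=np.eye(300))


def random_block_dosages(rng, n, props=(0.33, 0.58, 0.09)):
    anc = rng.choice(3, size=(n, 2), p=props)
    d = np.zeros((n, 3))
    for h in range(2):
        d[np.arange(n), anc[:, h]] += 1
    return d


class TestJointTest:
    def test_constant_dosages_are_degenerate(self, null_fit_300):
        _, null = null_fit_300
        d = np.tile([0.0, 2.0, 0.0], (300, 1))
        res = joint_ancestry_test(null, d)
        assert res.degenerate and res.p == 1.0 and res.df == 0

    def test_invariant_to_reference_ancestry_choice(self, null_fit_300):
        cohort, null = null_fit_300
        d = cohort.tracts.dosages[:, 3, :].astype(float)
        stats = [null.score_test(d[:, cols]).stat
                 for cols in ([0, 2], [1, 2], [0, 1])]
        assert abs(stats[0] - stats[1]) < 1e-8
        assert abs(stats[0] - stats[2]) < 1e-8

    def test_type_i_error_within_binomial_bounds(self, null_fit_300):
        _, null = null_fit_300
        rng = np.random.default_rng(5)
        n_tests = 2000
        rej = 0
        pvals = []
        for _ in range(n_tests):
            d = random_block_dosages(rng, 300)
            res = null.score_test(d[:, [0, 2]])
            pvals.append(res.p)
            rej += res.p < 0.05
        rate = rej / n_tests
        half = 1.96 * np.sqrt(0.05 * 0.95 / n_tests)
        assert abs(rate - 0.05) < half + 1e-12
        # and the p-values are uniform overall
        assert kstest(pvals, "uniform").pvalue > 0.01

    def test_malformed_dosages_rejected(self, null_fit_300):
        _, null = null_fit_300
        with pytest.raises(ValueError):
            joint_ancestry_test(null, np.ones((300, 3)))


class TestSingleAncestryTest:
    def test_null_effect_ci_covers_one(self):
        covered = 0
        for seed in range(20):
            rng = np.random.default_rng(1000 + seed)
            n = 300
            y = rng.integers(0, 2, n).astype(float)
            X = np.ones((n, 1))
            null = fit_null(y, X, grm=None)
            d = random_block_dosages(rng, n)[:, NAM]
            score, eff = single_ancestry_test(null, d)
            covered += eff.ci_low <= 1.0 <= eff.ci_high
        assert covered >= 18

    def test_constant_dosage_rejected(self, null_fit_300):
        _, null = null_fit_300
        with pytest.raises(ValueError, match="constant"):
            single_ancestry_test(null, np.full(300, 2.0))


def ancestry_driven_cohort(seed, n=1000, logor=np.log(0.3)):
    """Signal from an allelic effect at an ancestry-differentiated SNP."""
    m = 30
    rng = np.random.default_rng(seed)
    freqs = balding_nichols_freqs(m, (0.1, 0.1, 0.1), rng)
    causal = 15
    freqs[causal] = (0.10, 0.20, 0.90)
    cfg = SimConfig(
        n_samples=n, n_variants_per_chrom=m, chrom_lengths_cm=(150.0,),
        ancestral_allele_freqs=freqs,
        pheno=PhenoModel(allelic_logor=float(logor), causal_snp=causal),
        seed=seed,
    )
    return simulate_cohort(cfg), causal


class TestSNPTest:
    def test_conditioning_on_causal_snp_removes_ancestry_signal(self):
        uncond, cond = [], []
        for seed in range(10):
            cohort, causal = ancestry_driven_cohort(300 + seed)
            props = global_ancestry(cohort.tracts)
            X, _ = build_design(cohort.covariates, props)
            null = fit_null(cohort.phenotype, X, grm=None)
            blk = int(cohort.variants["block"].iloc[causal])
            d3 = cohort.tracts.dosages[:, blk, :].astype(float)
            uncond.append(joint_ancestry_test(null, d3).p)
            Xc = np.column_stack([X, cohort.genotypes[:, causal].astype(float)])
            null_c = fit_null(cohort.phenotype, Xc, grm=None)
            cond.append(joint_ancestry_test(null_c, d3).p)
        assert np.median(uncond) <= 1e-4
        assert np.median(cond) >= 0.01

    def test_null_snp_pvalues_uniform(self, null_fit_300):
        cohort, null = null_fit_300
        rng = np.random.default_rng(6)
        pvals = [
            snp_score_test(null, rng.binomial(2, 0.4, 300).astype(float))[0].p
            for _ in range(2000)
        ]
        assert kstest(pvals, "uniform").pvalue > 0.01

    def test_score_and_wald_z_agree_asymptotically(self):
        rng = np.random.default_rng(7)
        n = 5000
        d = rng.binomial(2, 0.3, n).astype(float)
        eta = -0.2 + 0.15 * d
        y = (rng.random(n) < 1 / (1 + np.exp(-eta))).astype(float)
        X = np.ones((n, 1))
        null = fit_null(y, X, grm=None)
        score, eff = snp_score_test(null, d, estimate_or=True)
        z_score = np.sign(eff.beta) * np.sqrt(score.stat)
        z_wald = eff.beta / eff.se
        assert abs(z_score - z_wald) < 0.1

    def test_collinear_conditioning_rejected(self, null_fit_300):
        _, null = null_fit_300
        with pytest.raises(ValueError, match="collinear"):
            snp_score_test(null, np.zeros(300), condition_on=np.ones((300, 1)))

    def test_missing_dosages_mean_imputed(self, null_fit_300):
        _, null = null_fit_300
        rng = np.random.default_rng(8)
        d = rng.binomial(2, 0.4, 300).astype(float)
        d_miss = d.copy()
        d_miss[:30] = -1
        res_missing, _ = snp_score_test(null, d_miss)
        d_imp = d.copy()
        d_imp[:30] = d[30:].mean()
        res_imputed, _ = snp_score_test(null, d_imp)
        assert res_missing.p == pytest.approx(res_imputed.p)


class TestGenomeScan:
    def test_null_cohorts_rarely_flag_significant_blocks(self):
        clean = 0
        for seed in range(20):
            cfg = SimConfig(n_samples=250, n_variants_per_chrom=0,
                            chrom_lengths_cm=(150.0, 150.0), seed=500 + seed)
            cohort = simulate_cohort(cfg)
            props = global_ancestry(cohort.tracts)
            X, _ = build_design(cohort.covariates, props)
            null = fit_null(cohort.phenotype, X, grm=None)
            res = admixture_scan(cohort.tracts, null, estimate_or="none")
            clean += int(res["significant"].sum() == 0)
        assert clean >= 19

    def test_causal_block_attains_scan_minimum(self, causal_cohort):
        props = global_ancestry(causal_cohort.tracts)
        X, _ = build_design(causal_cohort.covariates, props)
        null = fit_null(causal_cohort.phenotype, X, grm=None)
        res = admixture_scan(causal_cohort.tracts, null, estimate_or="none")
        top = res.loc[res["p"].idxmin()]
        blk = causal_cohort.truth["causal_block"]
        start = causal_cohort.tracts.blocks["start"].iloc[blk]
        assert top["start"] <= start < top["end"]
        assert top["chrom"] == causal_cohort.tracts.blocks["chrom"].iloc[blk]

    def test_power_across_replicates(self):
        hits = 0
        for seed in range(5):
            cfg = SimConfig(
                n_samples=800, n_variants_per_chrom=0,
                chrom_lengths_cm=tuple([150.0] * 4),
                pheno=PhenoModel(ancestry_logor=float(np.log(0.4)),
                                 causal_block=20),
                seed=900 + seed,
            )
            cohort = simulate_cohort(cfg)
            props = global_ancestry(cohort.tracts)
            X, _ = build_design(cohort.covariates, props)
            null = fit_null(cohort.phenotype, X, grm=None)
            res = admixture_scan(cohort.tracts, null, estimate_or="none")
            top = res.loc[res["p"].idxmin()]
            start = cohort.tracts.blocks["start"].iloc[20]
            chrom = cohort.tracts.blocks["chrom"].iloc[20]
            hits += int(top["chrom"] == chrom and top["start"] <= start < top["end"])
        assert hits >= 4

    def test_empty_variant_set_returns_empty_table(self, null_fit_300):
        _, null = null_fit_300
        out = association_scan(np.zeros((300, 0)), pd.DataFrame(columns=["chrom", "pos", "id"]), null)
        assert len(out) == 0

    def test_scan_results_ordered_by_position(self, causal_cohort):
        props = global_ancestry(causal_cohort.tracts)
        X, _ = build_design(causal_cohort.covariates, props)
        null = fit_null(causal_cohort.phenotype, X, grm=None)
        res = admixture_scan(causal_cohort.tracts, null, estimate_or="none")
        for _, sub in res.groupby("chrom"):
            assert (np.diff(sub["start"]) > 0).all()
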