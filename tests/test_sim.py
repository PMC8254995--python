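"""Generator contracts: tract process, genotypes, phenotype, relatives, noise."""

import numpy as np
import pytest

from admixscan.qc import global_ancestry
from admixscan.sim import (
    NAM,
    PhenoModel,
    RelatednessSpec,
    SimConfig,
    perturb_local_ancestry,
    simulate_cohort,
    simulate_genotypes,
    simulate_tracts,
)
from admixscan.sim.phenotype import draw_covariates


def make_config(**kw):
    kw.setdefault("n_samples", 200)
    kw.setdefault("n_variants_per_chrom", 0)
    kw.setdefault("chrom_lengths_cm", (150.0,))
    return SimConfig(**kw)


class TestTracts:
    def test_degenerate_proportions_give_pure_ancestry(self):
        tracts = simulate_tracts(make_config(global_props=(0.0, 1.0, 0.0), seed=1))
        assert (tracts.dosages[:, :, 1] == 2).all()
        assert (tracts.dosages[:, :, [0, 2]] == 0).all()
        # no observed ancestry switches anywhere: one block per chromosome
        assert tracts.n_blocks == 1

    def test_switch_counts_follow_poisson_rate(self):
        # g = 10 over a 1-Morgan chromosome: mean switches/haplotype = 10
        cfg = make_config(n_samples=1000, chrom_lengths_cm=(100.0,),
                          generations_g=10.0, seed=2)
        tracts = simulate_tracts(cfg)
        counts = tracts.sim_stats["switch_counts"]
        se = np.sqrt(10.0 / len(counts))
        assert abs(counts.mean() - 10.0) < 3 * se

    def test_segment_ancestries_match_global_props(self):
        cfg = make_config(n_samples=1000, global_props=(0.33, 0.58, 0.09), seed=3)
        tracts = simulate_tracts(cfg)
        props = global_ancestry(tracts)
        for k in range(3):
            se = props[:, k].std(ddof=1) / np.sqrt(props.shape[0])
            assert abs(props[:, k].mean() - cfg.global_props[k]) < 3 * se

    def test_mean_tract_length_approaches_inverse_g(self):
        cfg = make_config(n_samples=500, chrom_lengths_cm=(150.0,),
                          generations_g=10.0, seed=4)
        tracts = simulate_tracts(cfg)
        segs = tracts.sim_stats["segment_lengths_cm"]
        # pooled over haplotypes the mean is a ratio estimator with
        # expectation L/(gL+1) -> 1/g as the genome grows (here 9.375 cM)
        L, lam = 150.0, 10.0 / 100.0
        expect = L / (lam * L + 1)
        se = segs.std(ddof=1) / np.sqrt(len(segs))
        assert abs(segs.mean() - expect) < 3 * se
        assert abs(expect - 10.0) / 10.0 < 0.10  # close to 1/g already at 1.5 Morgan

    def test_dosage_conservation_and_tiling(self, related_cohort):
        d = related_cohort.tracts.dosages
        assert (d.sum(axis=2) == 2).all()
        blocks = related_cohort.tracts.blocks
        for _, sub in blocks.groupby("chrom"):
            assert (sub["start"].to_numpy()[1:] == sub["end"].to_numpy()[:-1]).all()

    def test_identical_seed_reproduces_everything(self):
        cfg = make_config(n_samples=50, n_variants_per_chrom=20, seed=9)
        a = simulate_cohort(cfg)
        b = simulate_cohort(cfg)
        assert (a.tracts.hap_anc == b.tracts.hap_anc).all()
        assert (a.genotypes == b.genotypes).all()
        assert (a.phenotype == b.phenotype).all()
        assert a.covariates.equals(b.covariates)

    def test_rejects_nonfinite_generations(self):
        with pytest.raises(ValueError):
            make_config(generations_g=np.inf)
        with pytest.raises(ValueError):
            make_config(generations_g=-1.0)


class TestGenotypes:
    def test_fixed_allele_gives_homozygous_alt(self):
        cfg = make_config(n_samples=30, n_variants_per_chrom=5, seed=5)
        tracts = simulate_tracts(cfg)
        freqs = np.ones((5, 3))
        cfg2 = cfg.replace(ancestral_allele_freqs=freqs)
        g, variants, hap = simulate_genotypes(tracts, cfg2, rng=0)
        assert (g == 2).all()

    def test_single_population_frequency_recovered(self):
        # all-AFR cohort, alt freq 0.9 in AFR: 2 variants x 1250 samples = 5000 alleles
        cfg = make_config(n_samples=1250, n_variants_per_chrom=2,
                          global_props=(1.0, 0.0, 0.0), seed=6)
        tracts = simulate_tracts(cfg)
        freqs = np.tile([0.9, 0.1, 0.1], (2, 1))
        g, variants, hap = simulate_genotypes(tracts, cfg.replace(
            ancestral_allele_freqs=freqs), rng=1)
        obs = hap.mean()
        se = np.sqrt(0.9 * 0.1 / hap.size)
        assert abs(obs - 0.9) < 3 * se

    def test_frequencies_stratified_by_true_local_ancestry(self):
        cfg = make_config(n_samples=600, n_variants_per_chrom=4, seed=7)
        tracts = simulate_tracts(cfg)
        freqs = np.tile([0.8, 0.5, 0.2], (4, 1))
        g, variants, hap = simulate_genotypes(
            tracts, cfg.replace(ancestral_allele_freqs=freqs), rng=2)
        anc = tracts.hap_anc[:, variants["block"].to_numpy(), :]
        for k, f in enumerate([0.8, 0.5, 0.2]):
            alleles = hap[anc == k]
            se = np.sqrt(f * (1 - f) / len(alleles))
            assert abs(alleles.mean() - f) < 3.5 * se


class TestPhenotype:
    def test_null_model_gives_half_cases(self):
        cfg = make_config(n_samples=2000, n_variants_per_chrom=0,
                          pheno=PhenoModel(intercept=0.0), seed=8)
        cohort = simulate_cohort(cfg)
        se = np.sqrt(0.25 / 2000)
        assert abs(cohort.phenotype.mean() - 0.5) < 3 * se

    def test_logistic_regression_recovers_protective_or(self):
        # confounding-free design: effect only through NAM dosage at one block
        import statsmodels.api as sm

        cfg = make_config(
            n_samples=5000, chrom_lengths_cm=(150.0, 150.0),
            pheno=PhenoModel(intercept=0.0, ancestry_logor=float(np.log(0.58)),
                             causal_block=10),
            seed=9,
        )
        cohort = simulate_cohort(cfg)
        dose = cohort.tracts.dosages[:, 10, NAM].astype(float)
        X = sm.add_constant(dose)
        fit = sm.Logit(cohort.phenotype, X).fit(disp=0)
        lo, hi = fit.conf_int()[1]
        assert lo <= np.log(0.58) <= hi

    def test_covariate_distributions_match_configuration(self):
        cfg = make_config(n_samples=5000)
        cov = draw_covariates(cfg, 5000, np.random.default_rng(0))
        assert abs(cov["age"].mean() - 73.6) < 3 * 9.0 / np.sqrt(5000)
        se_sex = np.sqrt(0.661 * 0.339 / 5000)
        assert abs(cov["sex"].mean() - 0.661) < 3 * se_sex
        assert cov["age"].between(35, 100).all()

    def test_missing_causal_block_rejected(self):
        cfg = make_config(pheno=PhenoModel(ancestry_logor=-0.5, causal_block=10**6))
        with pytest.raises(ValueError, match="causal_block"):
            simulate_cohort(cfg)


class TestRelatives:
    def test_zero_pairs_leaves_cohort_unchanged(self):
        cfg = make_config(n_samples=40, n_variants_per_chrom=10, seed=11)
        cohort = simulate_cohort(cfg)
        assert cohort.truth["kinship_pairs"] == []

    def test_duplicate_pair_has_truth_kinship_half(self):
        cfg = make_config(n_samples=40, n_variants_per_chrom=50,
                          relatedness=RelatednessSpec(n_duplicate=1), seed=12)
        cohort = simulate_cohort(cfg)
        (a, b, expected, kind) = cohort.truth["kinship_pairs"][0]
        assert kind == "duplicate" and expected == 0.5
        ia, ib = cohort.sample_ids.index(a), cohort.sample_ids.index(b)
        assert (cohort.genotypes[ia] == cohort.genotypes[ib]).all()

    def test_parent_offspring_haplotype_is_faithful_meiosis_copy(self, related_cohort):
        hap = related_cohort.truth["hap_alleles"]
        sources = related_cohort.truth["copy_sources"]
        ids = related_cohort.sample_ids
        kin_quarter = 0
        for a, b, expected, kind in related_cohort.truth["kinship_pairs"]:
            if kind != "parent_offspring":
                continue
            ip, io = ids.index(a), ids.index(b)
            src = sources[b]
            # brute-force IBD: the offspring's first haplotype must equal the
            # recorded parental haplotype at every variant
            copied = hap[ip, np.arange(hap.shape[1]), src]
            assert (hap[io, :, 0] == copied).all()
            # one of four haplotype pairs IBD at every locus: kinship 1/4
            kin_quarter += 1
        assert kin_quarter == 4

    def test_too_many_pairs_rejected(self):
        with pytest.raises(ValueError):
            make_config(n_samples=10,
                        relatedness=RelatednessSpec(n_parent_offspring=6))


class TestPerturbation:
    def test_zero_rate_is_identity(self, related_cohort):
        out = perturb_local_ancestry(related_cohort.tracts, 0.0, rng=0)
        assert (out.hap_anc == related_cohort.tracts.hap_anc).all()

    def test_rate_one_rejected(self, related_cohort):
        with pytest.raises(ValueError):
            perturb_local_ancestry(related_cohort.tracts, 1.0, rng=0)

    def test_relabeled_fraction_matches_rate(self):
        cfg = make_config(n_samples=700, chrom_lengths_cm=(150.0,) * 3, seed=13)
        tracts = simulate_tracts(cfg)
        out = perturb_local_ancestry(tracts, 0.05, rng=1)
        n_seg = out.sim_stats["n_segments"]
        frac = out.sim_stats["n_relabeled"] / n_seg
        se = np.sqrt(0.05 * 0.95 / n_seg)
        assert n_seg > 10000
        assert abs(frac - 0.05) < 3 * se
        assert (out.dosages.sum(axis=2) == 2).all()
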