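"""Relatedness estimation: KING-robust, partition, PCA projection, PC-adjustment."""

import itertools

import numpy as np
import pytest

from admixscan.relatedness import (
    KinshipMatrix,
    king_robust,
    partition_unrelated,
    pc_adjusted_kinship,
    pca_project,
    recursive_grm,
)
from admixscan.sim import RelatednessSpec, SimConfig, simulate_cohort
from admixscan.sim.genotypes import balding_nichols_freqs


def two_pop_genotypes(rng, n_per=40, m=2000, fst=0.2):
    """Two Balding-Nichols populations with strong differentiation."""
    p_anc = rng.uniform(0.2, 0.8, size=m)
    a = p_anc * (1 - fst) / fst
    b = (1 - p_anc) * (1 - fst) / fst
    p1 = np.clip(rng.beta(a, b), 0.01, 0.99)
    p2 = np.clip(rng.beta(a, b), 0.01, 0.99)
    g1 = rng.binomial(2, p1, size=(n_per, m))
    g2 = rng.binomial(2, p2, size=(n_per, m))
    return np.vstack([g1, g2]).astype(np.int8)


class TestKingRobust:
    def test_duplicate_sample_kinship_is_half(self):
        rng = np.random.default_rng(0)
        g = rng.binomial(2, rng.uniform(0.1, 0.9, 500), size=(10, 500)).astype(np.int8)
        g = np.vstack([g, g[0:1]])
        kin = king_robust(g)
        assert kin.values[0, -1] == pytest.approx(0.5)

    def test_parent_offspring_recovered(self):
        cfg = SimConfig(
            n_samples=80, n_variants_per_chrom=2500,
            chrom_lengths_cm=(150.0, 150.0),
            relatedness=RelatednessSpec(n_parent_offspring=6), seed=21,
        )
        cohort = simulate_cohort(cfg)
        kin = king_robust(cohort.genotypes, cohort.sample_ids)
        idx = {s: i for i, s in enumerate(cohort.sample_ids)}
        errs = [
            abs(kin.values[idx[a], idx[b]] - 0.25)
            for a, b, e, kind in cohort.truth["kinship_pairs"]
        ]
        assert np.mean(errs) < 0.02
        assert max(errs) < 0.04

    def test_cross_population_pairs_go_negative(self):
        g = two_pop_genotypes(np.random.default_rng(1))
        kin = king_robust(g)
        cross = kin.values[:40, 40:]
        assert cross.mean() < 0
        assert (cross < 0).mean() > 0.9

    def test_invariant_to_ref_alt_relabeling(self):
        rng = np.random.default_rng(2)
        g = rng.integers(0, 3, size=(15, 400)).astype(np.int8)
        flipped = g.copy()
        flip = rng.random(400) < 0.5
        flipped[:, flip] = 2 - flipped[:, flip]
        assert np.allclose(king_robust(g).values, king_robust(flipped).values)

    def test_needs_two_samples(self):
        with pytest.raises(ValueError):
            king_robust(np.array([[0, 1, 2]], dtype=np.int8))


class TestPartition:
    def test_all_unrelated_when_kinship_zero(self):
        kin = KinshipMatrix([f"S{i}" for i in range(6)], np.zeros((6, 6)))
        unrel, rel = partition_unrelated(kin)
        assert unrel.all() and not rel.any()

    def test_duplicate_pair_split(self):
        v = np.zeros((4, 4))
        v[0, 1] = v[1, 0] = 0.5
        np.fill_diagonal(v, 0.5)
        unrel, rel = partition_unrelated(KinshipMatrix([f"S{i}" for i in range(4)], v))
        assert unrel.sum() == 3
        assert unrel[0] != unrel[1]

    def test_matches_exhaustive_maximum_independent_set(self):
        # 3-clique {0,1,2} plus edge (3,4)
        v = np.zeros((5, 5))
        for i, j in [(0, 1), (0, 2), (1, 2), (3, 4)]:
            v[i, j] = v[j, i] = 0.1
        kin = KinshipMatrix([f"S{i}" for i in range(5)], v)
        unrel, _ = partition_unrelated(kin, threshold=0.025)
        adj = v >= 0.025
        best = 0
        for r in range(6):
            for subset in itertools.combinations(range(5), r):
                if not any(adj[i, j] for i in subset for j in subset if i < j):
                    best = max(best, len(subset))
        chosen = np.flatnonzero(unrel)
        assert not any(adj[i, j] for i in chosen for j in chosen if i < j)
        assert unrel.sum() == best == 2


class TestPCAProject:
    def test_related_copy_gets_identical_scores(self):
        rng = np.random.default_rng(3)
        g = rng.integers(0, 3, size=(20, 300)).astype(np.int8)
        g = np.vstack([g, g[0:1]])  # sample 20 duplicates sample 0
        unrel = np.ones(21, dtype=bool)
        unrel[20] = False
        pcs = pca_project(g, unrel, k=5)
        assert np.allclose(pcs.scores[20], pcs.scores[0], atol=1e-10)

    def test_pc1_separates_populations(self):
        g = two_pop_genotypes(np.random.default_rng(4), n_per=30, m=800)
        pcs = pca_project(g, np.ones(60, dtype=bool), k=4)
        label = np.r_[np.zeros(30), np.ones(30)]
        r = np.corrcoef(pcs.scores[:, 0], label)[0, 1]
        assert abs(r) > 0.9

    def test_full_rank_reconstruction_is_exact(self):
        rng = np.random.default_rng(5)
        g = rng.integers(0, 3, size=(12, 40)).astype(np.int8)
        unrel = np.ones(12, dtype=bool)
        pcs = pca_project(g, unrel, k=12)
        p = np.nanmean(np.where(g == -1, np.nan, g)[:, pcs.kept_variants], axis=0) / 2
        z = (g[:, pcs.kept_variants] - 2 * p) / np.sqrt(2 * p * (1 - p))
        assert np.allclose(pcs.scores @ pcs.loadings.T, z, atol=1e-8)

    def test_k_too_large_rejected(self):
        g = np.random.default_rng(6).integers(0, 3, (10, 50)).astype(np.int8)
        with pytest.raises(ValueError):
            pca_project(g, np.ones(10, dtype=bool), k=11)


class TestPCAdjustedKinship:
    def test_homogeneous_unrelated_mean_near_zero(self):
        rng = np.random.default_rng(7)
        p = rng.uniform(0.2, 0.8, 1000)
        g = rng.binomial(2, p, size=(60, 1000)).astype(np.int8)
        pcs = pca_project(g, np.ones(60, dtype=bool), k=4)
        kin = pc_adjusted_kinship(g, pcs)
        off = kin.values[np.triu_indices(60, 1)]
        assert abs(off.mean()) < 0.01

    def test_self_kinship_of_outbred_sample_near_half(self):
        rng = np.random.default_rng(8)
        p = rng.uniform(0.2, 0.8, 5000)
        g = rng.binomial(2, p, size=(200, 5000)).astype(np.int8)
        pcs = pca_project(g, np.ones(200, dtype=bool), k=4)
        kin = pc_adjusted_kinship(g, pcs)
        d = np.diag(kin.values)
        assert abs(d.mean() - 0.5) < 0.02
        assert np.all(np.abs(d - 0.5) < 0.04)

    def test_zero_pcs_reduces_to_frequency_centered_estimator(self):
        rng = np.random.default_rng(9)
        p = rng.uniform(0.2, 0.8, 200)
        g = rng.binomial(2, p, size=(8, 200)).astype(np.int8)
        pcs = pca_project(g, np.ones(8, dtype=bool), k=4)
        kin = pc_adjusted_kinship(g, pcs, n_pcs=0)
        # independent brute-force oracle: ratio-of-sums with sample frequencies
        phat = np.clip(g.mean(axis=0)[pcs.kept_variants] / 2, 0.01, 0.99)
        gk = g[:, pcs.kept_variants].astype(float)
        oracle = np.empty((8, 8))
        for i in range(8):
            for j in range(8):
                num = np.sum((gk[i] - 2 * phat) * (gk[j] - 2 * phat))
                den = 4 * np.sum(phat * (1 - phat))
                oracle[i, j] = num / den
        assert np.allclose(kin.values, oracle, atol=1e-10)

    def test_structured_parent_offspring_recovered(self, related_cohort):
        grm, pcs = recursive_grm(related_cohort.genotypes,
                                 sample_ids=related_cohort.sample_ids)
        idx = {s: i for i, s in enumerate(related_cohort.sample_ids)}
        errs = [
            abs(grm.values[idx[a], idx[b]] / 2 - expected)
            for a, b, expected, kind in related_cohort.truth["kinship_pairs"]
        ]
        assert np.mean(errs) < 0.03


class TestRecursiveGRM:
    def test_unstructured_cohort_is_fixed_point(self):
        # enough samples and variants that the unrelated partition is stable
        # between the KING-based and PC-adjusted-based iterations
        rng = np.random.default_rng(10)
        p = rng.uniform(0.2, 0.8, 4000)
        g = rng.binomial(2, p, size=(150, 4000)).astype(np.int8)
        g1, _ = recursive_grm(g, iterations=1)
        g2, _ = recursive_grm(g, iterations=2)
        assert np.abs(g1.values - g2.values).max() < 0.01

    def test_truth_relatives_excluded_from_final_unrelated_set(self, related_cohort):
        grm, pcs = recursive_grm(related_cohort.genotypes,
                                 sample_ids=related_cohort.sample_ids)
        idx = {s: i for i, s in enumerate(related_cohort.sample_ids)}
        for a, b, expected, kind in related_cohort.truth["kinship_pairs"]:
            assert not (pcs.unrelated[idx[a]] and pcs.unrelated[idx[b]])

    def test_symmetry_and_psd_contract(self, related_cohort):
        grm, _ = recursive_grm(related_cohort.genotypes,
                               sample_ids=related_cohort.sample_ids, ensure_psd=True)
        assert np.allclose(grm.values, grm.values.T)
        w = np.linalg.eigvalsh(grm.values)
        assert w.min() >= -1e-8
        assert np.isfinite(grm.min_eigenvalue)

    def test_kinship_recovery_over_replicate_cohorts(self):
        errs = []
        for seed in range(20):
            cfg = SimConfig(
                n_samples=70, n_variants_per_chrom=700,
                chrom_lengths_cm=(150.0, 150.0),
                relatedness=RelatednessSpec(n_parent_offspring=2, n_duplicate=1),
                seed=100 + seed,
            )
            cohort = simulate_cohort(cfg)
            grm, _ = recursive_grm(cohort.genotypes, sample_ids=cohort.sample_ids,
                                   ensure_psd=False)
            idx = {s: i for i, s in enumerate(cohort.sample_ids)}
            errs += [
                abs(grm.values[idx[a], idx[b]] / 2 - expected)
                for a, b, expected, kind in cohort.truth["kinship_pairs"]
            ]
        assert np.mean(errs) < 0.03
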