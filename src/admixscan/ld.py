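"""Pairwise linkage disequilibrium: r^2 and D' for biallelic SNP pairs.

From phased haplotypes the four haplotype frequencies are counted directly;
from unphased genotypes they are estimated by the classic EM algorithm over
the double-heterozygote ambiguity (converged at 1e-8).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np


@dataclass(frozen=True)
class LDResult:
    r2: float
    d_prime: float
    d: float
    p_a: float  # alt-allele frequency at the first SNP
    p_b: float


def _ld_from_hapfreq(pAB: float, pA: float, pB: float) -> LDResult:
    D = pAB - pA * pB
    denom = pA * (1 - pA) * pB * (1 - pB)
    r2 = (D * D) / denom
    if D >= 0:
        dmax = min(pA * (1 - pB), (1 - pA) * pB)
    else:
        dmax = min(pA * pB, (1 - pA) * (1 - pB))
    dprime = D / dmax if dmax > 0 else 0.0
    return LDResult(r2=float(r2), d_prime=float(dprime), d=float(D), p_a=pA, p_b=pB)


def ld_from_haplotypes(hap_a: np.ndarray, hap_b: np.ndarray) -> LDResult:
    """LD from phased alleles (0/1 arrays over haplotypes, aligned)."""
    a = np.asarray(hap_a, dtype=float)
    b = np.asarray(hap_b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("haplotype arrays must align")
    pA, pB = a.mean(), b.mean()
    if pA in (0.0, 1.0) or pB in (0.0, 1.0):
        raise ValueError("LD undefined for a monomorphic SNP")
    pAB = (a * b).mean()
    return _ld_from_hapfreq(pAB, pA, pB)


def em_haplotype_freqs(
    geno_a: np.ndarray, geno_b: np.ndarray, tol: float = 1e-8, max_iter: int = 1000
) -> np.ndarray:
    """EM haplotype-frequency estimates (pAB, pAb, paB, pab) from genotypes.

    Only double heterozygotes are phase-ambiguous; EM splits them between
    AB/ab and Ab/aB in proportion to the current frequency estimates.
    """
    ga = np.asarray(geno_a)
    gb = np.asarray(geno_b)
    keep = (ga >= 0) & (gb >= 0)
    ga, gb = ga[keep], gb[keep]
    n = len(ga)
    if n == 0:
        raise ValueError("no jointly observed genotypes")
    # fixed haplotype contributions from unambiguous genotype pairs
    counts = np.zeros(4)  # AB, Ab, aB, ab
    n_dh = 0
    for a, b in zip(ga, gb):
        if a == 1 and b == 1:
            n_dh += 1
            continue
        # each sample contributes two haplotypes with known phase
        n_A, n_B = int(a), int(b)
        for _ in range(2):
            ha = 1 if n_A == 2 else (0 if n_A == 0 else None)
            hb = 1 if n_B == 2 else (0 if n_B == 0 else None)
            if ha is None:
                ha, n_A = 1, 0  # the single A allele goes to this haplotype
            else:
                n_A -= ha
            if hb is None:
                hb, n_B = 1, 0
            else:
                n_B -= hb
            counts[(1 - ha) * 2 + (1 - hb)] += 1
    f = np.full(4, 0.25)
    for _ in range(max_iter):
        cis = f[0] * f[3]
        trans = f[1] * f[2]
        w = cis / (cis + trans) if (cis + trans) > 0 else 0.5
        new = counts.copy()
        new[0] += n_dh * w
        new[3] += n_dh * w
        new[1] += n_dh * (1 - w)
        new[2] += n_dh * (1 - w)
        new /= new.sum()
        if np.max(np.abs(new - f)) < tol:
            f = new
            break
        f = new
    return f


def ld_from_genotypes(geno_a: np.ndarray, geno_b: np.ndarray) -> LDResult:
    """LD from unphased genotypes via EM haplotype frequencies."""
    ga = np.asarray(geno_a)
    gb = np.asarray(geno_b)
    va = ga[ga >= 0]
    vb = gb[gb >= 0]
    if len(np.unique(va)) < 2 or len(np.unique(vb)) < 2:
        raise ValueError("LD undefined for a monomorphic SNP")
    f = em_haplotype_freqs(ga, gb)
    pA = f[0] + f[1]
    pB = f[0] + f[2]
    return _ld_from_hapfreq(f[0], pA, pB)


def ld_stats(
    snp_a: np.ndarray, snp_b: np.ndarray, phased: bool = False
) -> LDResult:
    """r^2 and D' for one SNP pair, phased (haplotype) or unphased (EM)."""
    if phased:
        return ld_from_haplotypes(snp_a, snp_b)
    return ld_from_genotypes(snp_a, snp_b)
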