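"""Effective number of tests and Bonferroni thresholds for admixture scans.

Recent admixture creates very long-range LD among local-ancestry dosages,
so the number of *independent* admixture-mapping tests is far below the
block count.  Per ancestry, the effective count is estimated from an
autoregressive model fit to the genome-ordered vector of per-block mean
dosages: for AR(1) with coefficient phi, a chromosome of M blocks
contributes M*(1-phi)/(1+phi) effective tests (the variance-ratio of the
mean of an AR(1) series).  The three per-ancestry counts are combined as
the sum of the two largest — the third is redundant because the dosage
triple sums to 2 — and the scan threshold is alpha divided by the combined
count.  For SNP association within a region, the effective count is the
number of leading eigenvalues of the SNP correlation matrix needed to
explain 99.5% of its variance (simpleM-style).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.linalg import solve_toeplitz

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class EffectiveTests:
    per_ancestry: tuple[float, float, float]  # AFR, EUR, NAM
    combined: float
    alpha: float
    threshold: float


def _yule_walker(x: np.ndarray, order: int) -> np.ndarray:
    """AR coefficients by Yule-Walker from the sample autocovariances."""
    x = x - x.mean()
    n = len(x)
    acov = np.array([np.dot(x[: n - k], x[k:]) / n for k in range(order + 1)])
    if acov[0] <= 0:
        return np.zeros(order)
    return solve_toeplitz(acov[:-1], acov[1:])


def _ar_mean_variance_ratio(phi: np.ndarray, acov_ratio: np.ndarray | None = None) -> float:
    """Ratio (effective M) / M for the mean of a long AR(p) series.

    Equals gamma0 * (1 - sum(phi))^2 / sigma2_e, the ratio of the process
    variance to its spectral density at frequency zero; for AR(1) this is
    (1 - phi) / (1 + phi).
    """
    p = len(phi)
    if p == 0:
        return 1.0
    if acov_ratio is None:
        raise ValueError("autocovariance ratios required for order > 0")
    # sigma2_e / gamma0 = 1 - sum_k phi_k * rho_k
    s2_over_g0 = 1.0 - float(np.dot(phi, acov_ratio[1 : p + 1]))
    if s2_over_g0 <= 0:
        return 0.0
    return float((1.0 - phi.sum()) ** 2 / s2_over_g0)


def ar_effective_tests(
    dosage_sequence: np.ndarray,
    chrom: np.ndarray | None = None,
    order: int = 1,
) -> float:
    """Effective test count for one ancestry's genome-ordered dosage vector.

    ``dosage_sequence`` is the per-block mean dosage (averaged over samples)
    in genome order; ``chrom`` labels blocks by chromosome so that
    chromosomes are modeled independently and their effective counts summed.
    Each chromosome needs >= 10 blocks.  A constant sequence contributes an
    effective count of 1 (a single test).  Counts are clipped to
    [1, M_chromosome].
    """
    x = np.asarray(dosage_sequence, dtype=float)
    if chrom is None:
        chrom = np.zeros(len(x))
    chrom = np.asarray(chrom)
    total = 0.0
    for c in pd.unique(chrom):
        xc = x[chrom == c]
        M = len(xc)
        if M < 10:
            raise ValueError(f"chromosome {c!r} has {M} < 10 blocks")
        if np.std(xc) == 0:
            logger.info("constant dosage sequence on chromosome %r; count = 1", c)
            total += 1.0
            continue
        xd = xc - xc.mean()
        acov = np.array([np.dot(xd[: M - k], xd[k:]) / M for k in range(order + 1)])
        phi = np.atleast_1d(_yule_walker(xc, order))
        ratio = _ar_mean_variance_ratio(phi, acov / acov[0])
        total += float(np.clip(M * ratio, 1.0, M))
    return total


def combine_effective_tests(counts) -> float:
    """Sum of the two largest per-ancestry effective counts."""
    c = np.asarray(counts, dtype=float)
    if c.shape != (3,):
        raise ValueError("exactly three per-ancestry counts required")
    if np.any(c <= 0):
        raise ValueError("counts must be positive")
    return float(np.sort(c)[-2:].sum())


def bonferroni_threshold(alpha: float, combined_count: float) -> float:
    """Scan-wide significance threshold alpha / effective count."""
    if not (0.0 < alpha < 1.0):
        raise ValueError("alpha must lie in (0, 1)")
    if combined_count < 1:
        raise ValueError("effective count must be >= 1")
    return alpha / combined_count


def effective_tests_for_scan(
    tracts, alpha: float = 0.05, order: int = 1
) -> EffectiveTests:
    """Per-ancestry AR effective counts for a cohort's local-ancestry blocks."""
    d = tracts.dosages.astype(float)
    chrom = tracts.blocks["chrom"].to_numpy()
    per = tuple(
        ar_effective_tests(d[:, :, k].mean(axis=0), chrom=chrom, order=order)
        for k in range(3)
    )
    combined = combine_effective_tests(per)
    return EffectiveTests(
        per_ancestry=per,
        combined=combined,
        alpha=alpha,
        threshold=bonferroni_threshold(alpha, combined),
    )


def regional_effective_tests(
    genotypes: np.ndarray, var_explained: float = 0.995, alpha: float = 0.05
) -> tuple[int, float, float]:
    """simpleM-style effective count for a region's SNP set.

    Counts the leading eigenvalues of the SNP correlation matrix needed to
    explain ``var_explained`` of total variance.  Duplicate SNP columns are
    collapsed first.  Returns (count, significant_threshold,
    suggestive_threshold) = (Meff, alpha/Meff, 1/Meff).
    """
    g = np.asarray(genotypes, dtype=float)
    if g.ndim != 2 or g.shape[1] == 0:
        raise ValueError("region SNP set is empty")
    g = np.where(g < 0, np.nan, g)
    col_mean = np.nanmean(g, axis=0)
    g = np.where(np.isfinite(g), g, col_mean)
    sd = g.std(axis=0)
    keep = sd > 0
    g = g[:, keep]
    if g.shape[1] == 0:
        raise ValueError("no polymorphic SNPs in region")
    _, unique_idx = np.unique(g.round(12), axis=1, return_index=True)
    if len(unique_idx) < g.shape[1]:
        logger.info("collapsed %d duplicate SNP columns", g.shape[1] - len(unique_idx))
        g = g[:, np.sort(unique_idx)]
    corr = np.corrcoef(g, rowvar=False)
    w = np.linalg.eigvalsh(np.atleast_2d(corr))[::-1]
    w = np.clip(w, 0, None)
    cum = np.cumsum(w) / w.sum()
    meff = int(np.searchsorted(cum, var_explained) + 1)
    return meff, alpha / meff, 1.0 / meff
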