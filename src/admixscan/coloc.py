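"""Approximate-Bayes-factor colocalization of two association signals.

Per SNP, the Wakefield approximate Bayes factor compares association
against the null under a normal prior N(0, W) on the effect:

    log ABF = 0.5 * log(V / (V + W)) + 0.5 * z^2 * W / (V + W)

with V = se^2 and z = beta / se.  Over a region with one causal variant
per trait at most, the five hypotheses (H0 no association; H1/H2 one trait
only; H3 both traits, different SNPs; H4 both traits, one shared SNP) get
posterior probabilities from per-SNP ABF sums weighted by priors
p1, p2 (per-SNP association with one trait) and p12 (shared causal SNP).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import logsumexp

logger = logging.getLogger(__name__)

#: Default effect-prior standard deviations by trait type.
PRIOR_SD = {"cc": 0.2, "quant": 0.15}


@dataclass(frozen=True)
class SummaryStats:
    """Per-SNP association summary statistics for one trait.

    Provide beta and se; alternatively z plus sample size n and allele
    frequency f, from which se is reconstructed as for a standardized
    quantitative trait: se = 1 / sqrt(2 f (1-f) n).
    """

    snp_ids: tuple
    beta: np.ndarray
    se: np.ndarray
    trait_type: str = "cc"  # 'cc' (case-control) or 'quant'

    def __post_init__(self) -> None:
        if len(set(self.snp_ids)) != len(self.snp_ids):
            raise ValueError("SNP ids must be unique")
        if len(self.snp_ids) != len(self.beta) or len(self.beta) != len(self.se):
            raise ValueError("snp_ids, beta, se must align")
        if np.any(~np.isfinite(self.beta)) or np.any(~np.isfinite(self.se)):
            raise ValueError("beta and se must be finite")
        if np.any(self.se <= 0):
            raise ValueError("standard errors must be positive")
        if self.trait_type not in PRIOR_SD:
            raise ValueError("trait_type must be 'cc' or 'quant'")

    @classmethod
    def from_z(cls, snp_ids, z, n, freq, trait_type="quant") -> "SummaryStats":
        z = np.asarray(z, dtype=float)
        freq = np.asarray(freq, dtype=float)
        se = 1.0 / np.sqrt(2.0 * freq * (1.0 - freq) * np.asarray(n, dtype=float))
        return cls(tuple(snp_ids), beta=z * se, se=se, trait_type=trait_type)

    @classmethod
    def from_table(cls, df: pd.DataFrame, trait_type="cc") -> "SummaryStats":
        cols = {c.lower(): c for c in df.columns}
        ids = tuple(df[cols.get("snp", "snp")].astype(str))
        if "beta" in cols and "se" in cols:
            return cls(ids, df[cols["beta"]].to_numpy(float),
                       df[cols["se"]].to_numpy(float), trait_type)
        if {"z", "n", "freq"} <= set(cols):
            return cls.from_z(ids, df[cols["z"]], df[cols["n"]], df[cols["freq"]],
                              trait_type)
        raise ValueError("summary table needs (beta, se) or (z, n, freq) columns")


@dataclass
class ColocResult:
    snp_ids: tuple
    labf1: np.ndarray
    labf2: np.ndarray
    pp: dict = field(default_factory=dict)  # 'PP0'..'PP4'
    priors: tuple = (1e-4, 1e-4, 1e-5)
    n_shared: int = 0


def coloc_scatter(stats1: SummaryStats, stats2: SummaryStats, path) -> None:
    """Side-by-side -log10(p) scatter of the two traits over shared SNPs."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt
    from scipy.stats import norm

    shared = [s for s in stats1.snp_ids if s in set(stats2.snp_ids)]
    i1 = [stats1.snp_ids.index(s) for s in shared]
    i2 = [stats2.snp_ids.index(s) for s in shared]
    lp1 = -norm.logsf(np.abs(stats1.beta[i1] / stats1.se[i1])) / np.log(10) - np.log10(2)
    lp2 = -norm.logsf(np.abs(stats2.beta[i2] / stats2.se[i2])) / np.log(10) - np.log10(2)
    fig, ax = plt.subplots(figsize=(4.5, 4.5))
    ax.scatter(lp1, lp2, s=10)
    ax.set_xlabel("trait 1: -log10 p")
    ax.set_ylabel("trait 2: -log10 p")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def per_snp_table(result: ColocResult) -> pd.DataFrame:
    """Per-SNP log ABFs for both traits as a tidy table."""
    return pd.DataFrame(
        {"snp": result.snp_ids, "labf1": result.labf1, "labf2": result.labf2}
    )


def wakefield_abf(beta: float, se: float, prior_sd: float) -> float:
    """Log approximate Bayes factor of association vs null for one SNP."""
    beta = np.asarray(beta, dtype=float)
    se = np.asarray(se, dtype=float)
    if np.any(~np.isfinite(beta)) or np.any(~np.isfinite(se)) or np.any(se <= 0):
        raise ValueError("beta and se must be finite with se > 0")
    if not np.all(np.isfinite(prior_sd)) or prior_sd < 0:
        raise ValueError("prior_sd must be finite and non-negative")
    V = se**2
    W = prior_sd**2
    z2 = (beta / se) ** 2
    return 0.5 * np.log(V / (V + W)) + 0.5 * z2 * W / (V + W)


def _logdiff(a: float, b: float) -> float:
    """log(exp(a) - exp(b)) for a > b."""
    if b >= a:
        return -np.inf
    return a + np.log1p(-np.exp(b - a))


def coloc_abf(
    stats1: SummaryStats,
    stats2: SummaryStats,
    p1: float = 1e-4,
    p2: float = 1e-4,
    p12: float = 1e-5,
    prior_sd1: float | None = None,
    prior_sd2: float | None = None,
) -> ColocResult:
    """Posterior probabilities PP0..PP4 from two summary-statistic sets.

    Analysis is restricted to the intersection of SNP ids (count logged);
    an empty intersection is an error.  PPs are exactly normalized.
    """
    shared = [s for s in stats1.snp_ids if s in set(stats2.snp_ids)]
    if not shared:
        raise ValueError("no shared SNP ids between the two traits")
    logger.info("colocalization over %d shared SNPs", len(shared))
    i1 = [stats1.snp_ids.index(s) for s in shared]
    i2 = [stats2.snp_ids.index(s) for s in shared]
    w1 = PRIOR_SD[stats1.trait_type] if prior_sd1 is None else prior_sd1
    w2 = PRIOR_SD[stats2.trait_type] if prior_sd2 is None else prior_sd2
    l1 = wakefield_abf(stats1.beta[i1], stats1.se[i1], w1)
    l2 = wakefield_abf(stats2.beta[i2], stats2.se[i2], w2)

    s1 = logsumexp(l1)
    s2 = logsumexp(l2)
    s12 = logsumexp(l1 + l2)
    lh = np.array(
        [
            0.0,
            np.log(p1) + s1,
            np.log(p2) + s2,
            np.log(p1) + np.log(p2) + _logdiff(s1 + s2, s12),
            np.log(p12) + s12,
        ]
    )
    pp = np.exp(lh - logsumexp(lh))
    pp /= pp.sum()
    return ColocResult(
        snp_ids=tuple(shared),
        labf1=l1,
        labf2=l2,
        pp={f"PP{k}": float(pp[k]) for k in range(5)},
        priors=(p1, p2, p12),
        n_shared=len(shared),
    )
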