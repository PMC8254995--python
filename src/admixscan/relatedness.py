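"""Ancestry-robust genetic relatedness estimation.

The recursive procedure: (1) KING-robust kinship from heterozygote
concordance (robust to allele-frequency misspecification but biased by
admixture for unrelated pairs, which can go negative); (2) partition the
cohort into a mutually-unrelated set and the rest; (3) PCA on the unrelated
set with projection of related samples; (4) kinship re-estimated from
genotype residuals about individual-specific allele frequencies predicted
from the PCs, removing the structure component; (5) repeat the partition on
the adjusted kinship.  The final GRM is twice the adjusted kinship.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np

from admixscan.sim.cohort import MISSING

logger = logging.getLogger(__name__)

#: Default kinship threshold separating "unrelated" (3rd-degree bound).
UNRELATED_THRESHOLD = 0.025


def auto_unrelated_threshold(kinship_values: np.ndarray, floor: float = UNRELATED_THRESHOLD) -> float:
    """Noise-aware partition threshold: max(floor, 3 x robust null SD).

    With dense genotyping the 3rd-degree bound 0.025 separates relatives from
    noise; at small variant counts the sampling SD of pairwise kinship can
    exceed it, and a fixed cut would misclassify most of the cohort as
    related.  The null spread is estimated from the off-diagonal by the
    median absolute deviation, which is insensitive to the (few) true
    relative pairs, and the cut is set so the expected number of
    false-positive "related" pairs across all n(n-1)/2 pairs is ~0.01,
    keeping the partition stable between recursion iterations.
    """
    from scipy.stats import norm

    k = np.nan_to_num(kinship_values, nan=0.0)
    n_pairs = k.shape[0] * (k.shape[0] - 1) // 2
    off = k[np.triu_indices(k.shape[0], 1)]
    mad_sd = 1.4826 * np.median(np.abs(off - np.median(off)))
    z = max(3.0, float(norm.ppf(1.0 - 0.01 / max(n_pairs, 1))))
    return float(max(floor, np.median(off) + z * mad_sd))


@dataclass
class KinshipMatrix:
    sample_ids: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        v = self.values
        if v.shape[0] != v.shape[1] or v.shape[0] != len(self.sample_ids):
            raise ValueError("kinship matrix must be square over sample ids")
        if not np.allclose(v, v.T, equal_nan=True):
            raise ValueError("kinship matrix must be symmetric")


@dataclass
class PCResult:
    sample_ids: list[str]
    scores: np.ndarray  # samples x k
    loadings: np.ndarray  # variants x k
    variance_explained: np.ndarray
    unrelated: np.ndarray  # boolean mask over samples
    center: np.ndarray = field(default=None)  # per-variant 2*p from unrelated set
    scale: np.ndarray = field(default=None)
    kept_variants: np.ndarray = field(default=None)


@dataclass
class GRM:
    sample_ids: list[str]
    values: np.ndarray
    min_eigenvalue: float = np.nan
    clipped_mass: float = 0.0


def king_robust(genotypes: np.ndarray, sample_ids: list[str] | None = None) -> KinshipMatrix:
    """Pairwise KING-robust kinship from heterozygote concordance.

    phi_ij = (N_het,het - 2 * N_opposing_hom) / (N_het_i + N_het_j), counts
    taken over variants observed in both samples.  Duplicates give 0.5,
    parent-offspring ~0.25; pairs from diverged populations go negative.
    Pairs with no jointly-observed heterozygous variant get NaN and are
    flagged in the log.
    """
    g = np.asarray(genotypes)
    n, m = g.shape
    if n < 2 or m < 1:
        raise ValueError("need >= 2 samples and >= 1 variant")
    if sample_ids is None:
        sample_ids = [f"S{i:05d}" for i in range(n)]
    obs = (g != MISSING).astype(np.float64)
    het = (g == 1).astype(np.float64)
    hom0 = (g == 0).astype(np.float64)
    hom2 = (g == 2).astype(np.float64)
    n_hethet = het @ het.T
    n_opp = hom0 @ hom2.T
    n_opp = n_opp + n_opp.T
    het_i = het @ obs.T  # het count of i over variants observed in j
    denom = het_i + het_i.T
    with np.errstate(divide="ignore", invalid="ignore"):
        phi = (n_hethet - 2.0 * n_opp) / denom
    bad = ~np.isfinite(phi)
    if bad.any():
        logger.warning("%d sample pairs have undefined KING-robust kinship", int(bad.sum()) // 2)
        phi[bad] = np.nan
    np.fill_diagonal(phi, 0.5)  # self-kinship of a non-inbred diploid
    phi = 0.5 * (phi + phi.T)
    return KinshipMatrix(sample_ids=list(sample_ids), values=phi)


def partition_unrelated(
    kinship: KinshipMatrix, threshold: float = UNRELATED_THRESHOLD
) -> tuple[np.ndarray, np.ndarray]:
    """Split samples into a mutually-unrelated set and its complement.

    Greedy: repeatedly discard the sample with the most remaining kinship
    ties >= threshold, breaking ties by discarding the larger sample index,
    until no tie remains.  Missing kinship entries are treated as 0.
    Returns boolean masks (unrelated, related).
    """
    k = np.nan_to_num(kinship.values, nan=0.0).copy()
    n = k.shape[0]
    np.fill_diagonal(k, 0.0)
    adj = k >= threshold
    alive = np.ones(n, dtype=bool)
    deg = adj.sum(axis=1).astype(np.int64)
    while True:
        if not (deg[alive] > 0).any():
            break
        cand = np.flatnonzero(alive & (deg == deg[alive].max()))
        victim = cand[-1]  # ascending-id tie-break: keep the smallest ids
        alive[victim] = False
        deg[adj[victim]] -= 1
        deg[victim] = 0
    return alive, ~alive


def pca_project(
    genotypes: np.ndarray,
    unrelated: np.ndarray,
    k: int = 10,
    sample_ids: list[str] | None = None,
) -> PCResult:
    """PCA on the unrelated set with projection of related samples.

    Variants are centered and scaled by the unrelated-set allele frequencies
    (2p, sqrt(2p(1-p))); monomorphic (in the unrelated set) variants are
    dropped.  Scores for related samples use the unrelated-set loadings and
    scaling, so a related sample identical to an unrelated one gets
    identical scores.
    """
    g = np.asarray(genotypes, dtype=float)
    n, m = g.shape
    unrelated = np.asarray(unrelated, dtype=bool)
    if sample_ids is None:
        sample_ids = [f"S{i:05d}" for i in range(n)]
    if k > min(int(unrelated.sum()), m):
        raise ValueError("k exceeds min(n_unrelated, n_variants)")
    gm = np.where(g == MISSING, np.nan, g)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        p = np.nanmean(gm[unrelated], axis=0) / 2.0
    keep = np.isfinite(p) & (p > 0) & (p < 1)
    if not keep.all():
        logger.info("dropping %d monomorphic/unobserved variants for PCA", int((~keep).sum()))
    gm = gm[:, keep]
    p = p[keep]
    center = 2.0 * p
    scale = np.sqrt(2.0 * p * (1.0 - p))
    z = (gm - center) / scale
    z = np.where(np.isfinite(z), z, 0.0)  # mean imputation of missing
    zu = z[unrelated]
    u, s, vt = np.linalg.svd(zu, full_matrices=False)
    loadings = vt[:k].T
    ve = (s**2) / np.sum(s**2)
    scores = z @ loadings
    return PCResult(
        sample_ids=list(sample_ids),
        scores=scores,
        loadings=loadings,
        variance_explained=ve[:k],
        unrelated=unrelated,
        center=center,
        scale=scale,
        kept_variants=np.flatnonzero(keep),
    )


def pc_adjusted_kinship(
    genotypes: np.ndarray, pcs: PCResult, n_pcs: int = 4
) -> KinshipMatrix:
    """Kinship from genotype residuals about PC-predicted allele frequencies.

    Each variant's dosages are regressed (on the unrelated set) on an
    intercept plus the first ``n_pcs`` PC scores; the fit predicts an
    individual-specific expected dosage 2*mu_im for everyone.  Kinship is

        phi_ij = sum_m (g_im - 2 mu_im)(g_jm - 2 mu_jm)
                 / (4 * sum_m sqrt(mu_im(1-mu_im) mu_jm(1-mu_jm)))

    which removes the structure component captured by the PCs.  Predicted
    frequencies outside (0.01, 0.99) are clipped and counted.
    """
    if pcs.scores.shape[1] < n_pcs:
        raise ValueError(f"PCResult must carry >= {n_pcs} components")
    g = np.asarray(genotypes, dtype=float)[:, pcs.kept_variants]
    gm = np.where(g == MISSING, np.nan, g)
    X = np.column_stack([np.ones(g.shape[0]), pcs.scores[:, :n_pcs]])
    unrel = pcs.unrelated
    # per-variant OLS on the unrelated set; mean-impute missing for the solve
    gu = gm[unrel]
    col_mean = np.nanmean(gu, axis=0)
    gu = np.where(np.isfinite(gu), gu, col_mean)
    beta, *_ = np.linalg.lstsq(X[unrel], gu, rcond=None)
    mu = (X @ beta) / 2.0
    n_clip = int(((mu < 0.01) | (mu > 0.99)).sum())
    if n_clip:
        logger.info("clipped %d fitted allele frequencies to [0.01, 0.99]", n_clip)
    mu = np.clip(mu, 0.01, 0.99)
    resid = np.where(np.isfinite(gm), gm, 2 * mu) - 2 * mu
    sd = np.sqrt(mu * (1.0 - mu))
    num = resid @ resid.T
    den = 4.0 * (sd @ sd.T)
    phi = num / den
    phi = 0.5 * (phi + phi.T)
    return KinshipMatrix(sample_ids=list(pcs.sample_ids), values=phi)


def recursive_grm(
    genotypes: np.ndarray,
    iterations: int = 2,
    n_pcs: int = 4,
    k_report: int = 10,
    threshold: float | str = "auto",
    sample_ids: list[str] | None = None,
    ensure_psd: bool = True,
) -> tuple[GRM, PCResult]:
    """Recursive ancestry-robust GRM.

    Iteration 1 partitions on KING-robust kinship; later iterations
    partition on the previous PC-adjusted kinship.  ``threshold`` may be a
    kinship value or "auto" (max of the 3rd-degree bound 0.025 and three
    robust null SDs, so sparse variant panels do not collapse the unrelated
    set).  Returns the final GRM (2 x adjusted kinship, optionally
    eigenvalue-clipped to PSD) and the final PCResult.
    """
    if iterations < 1:
        raise ValueError("iterations >= 1 required")
    g = np.asarray(genotypes)
    n = g.shape[0]
    if sample_ids is None:
        sample_ids = [f"S{i:05d}" for i in range(n)]
    kin = king_robust(g, sample_ids)
    prev_unrel = None
    pcs = None
    for it in range(iterations):
        thr = auto_unrelated_threshold(kin.values) if threshold == "auto" else threshold
        unrel, _ = partition_unrelated(kin, thr)
        k_eff = min(max(k_report, n_pcs), int(unrel.sum()), g.shape[1])
        pcs = pca_project(g, unrel, k=k_eff, sample_ids=sample_ids)
        kin = pc_adjusted_kinship(g, pcs, n_pcs=n_pcs)
        if prev_unrel is not None and (unrel == prev_unrel).all():
            break
        prev_unrel = unrel
    values = 2.0 * kin.values
    min_eig = np.nan
    clipped = 0.0
    if ensure_psd:
        w, v = np.linalg.eigh(values)
        min_eig = float(w.min())
        if min_eig < 0:
            clipped = float(-w[w < 0].sum())
            w = np.clip(w, 0.0, None)
            values = (v * w) @ v.T
            values = 0.5 * (values + values.T)
    grm = GRM(
        sample_ids=list(sample_ids),
        values=values,
        min_eigenvalue=min_eig,
        clipped_mass=clipped,
    )
    return grm, pcs
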