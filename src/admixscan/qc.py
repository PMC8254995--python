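"""Sample and variant quality control, and global-ancestry summarization.

Filters mirror standard array-QC practice for admixed case-control cohorts:
variants with genotype missingness > 5% are dropped first, then samples
missing > 5% of the remaining genotypes; heterozygosity outliers are samples
extreme for *both* the inbreeding coefficient F (> 0.12) and the
heterozygosity rate (< 0.28); duplicates are flagged at kinship >= 0.45.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from admixscan.sim.cohort import MISSING
from admixscan.sim.config import GeneticMap
from admixscan.sim.tracts import LocalAncestryMatrix


@dataclass(frozen=True)
class QCThresholds:
    variant_missing_max: float = 0.05
    sample_missing_max: float = 0.05
    f_max: float = 0.12
    het_min: float = 0.28
    duplicate_kinship_min: float = 0.45

    def __post_init__(self) -> None:
        for name in ("variant_missing_max", "sample_missing_max", "het_min"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name} must lie in [0, 1]")


@dataclass
class QCReport:
    """Counts along the filter chain plus per-sample statistics."""

    n_variants_before: int = 0
    n_variants_after: int = 0
    n_samples_before: int = 0
    n_samples_after: int = 0
    dropped_variants: np.ndarray = field(default_factory=lambda: np.array([], dtype=int))
    dropped_samples: np.ndarray = field(default_factory=lambda: np.array([], dtype=int))
    per_sample: pd.DataFrame | None = None
    flagged_samples: list = field(default_factory=list)

    def to_dict(self) -> dict:
        d = {
            "n_variants_before": self.n_variants_before,
            "n_variants_after": self.n_variants_after,
            "n_samples_before": self.n_samples_before,
            "n_samples_after": self.n_samples_after,
            "dropped_variants": self.dropped_variants.tolist(),
            "dropped_samples": self.dropped_samples.tolist(),
            "flagged_samples": list(self.flagged_samples),
        }
        if self.per_sample is not None:
            d["per_sample"] = self.per_sample.to_dict(orient="list")
        return d


def filter_missingness(
    genotypes: np.ndarray, thresholds: QCThresholds = QCThresholds()
) -> tuple[np.ndarray, QCReport]:
    """Drop high-missingness variants, then high-missingness samples.

    The order matters for survivor counts and is fixed: variants first, then
    samples evaluated over the surviving variants.  Because removing samples
    can raise the missing fraction of a remaining variant past the cut, the
    variant->sample pass repeats until nothing changes, making the filter
    idempotent.  Thresholds are strict (a variant at exactly the maximum is
    kept).  Returns the filtered matrix and a report with original indices
    of everything dropped.
    """
    g = np.asarray(genotypes)
    n, m = g.shape
    report = QCReport(n_variants_before=m, n_samples_before=n)
    if (g == MISSING).all():
        warnings.warn("genotype matrix entirely missing; returning empty result")
        report.dropped_variants = np.arange(m)
        report.dropped_samples = np.arange(n)
        return g[:0, :0], report
    keep_v = np.ones(m, dtype=bool)
    keep_s = np.ones(n, dtype=bool)
    while True:
        sub = g[np.ix_(keep_s, keep_v)]
        miss = sub == MISSING
        bad_v = miss.mean(axis=0) > thresholds.variant_missing_max
        if bad_v.any():
            keep_v[np.flatnonzero(keep_v)[bad_v]] = False
            sub = g[np.ix_(keep_s, keep_v)]
            miss = sub == MISSING
        bad_s = (
            miss.mean(axis=1) > thresholds.sample_missing_max
            if sub.shape[1]
            else np.zeros(int(keep_s.sum()), dtype=bool)
        )
        if bad_s.any():
            keep_s[np.flatnonzero(keep_s)[bad_s]] = False
        if not bad_v.any() and not bad_s.any():
            break
    report.dropped_variants = np.flatnonzero(~keep_v)
    report.dropped_samples = np.flatnonzero(~keep_s)
    out = g[np.ix_(keep_s, keep_v)]
    report.n_variants_after = out.shape[1]
    report.n_samples_after = out.shape[0]
    return out, report


def heterozygosity_stats(
    genotypes: np.ndarray, allele_freq: np.ndarray | None = None
) -> pd.DataFrame:
    """Per-sample inbreeding coefficient F and heterozygosity rate.

    F = (O_hom - E_hom) / (m_obs - E_hom) with the expected homozygote count
    under Hardy-Weinberg computed from allele frequencies.  Frequencies are
    estimated from the sample unless ``allele_freq`` is given; passing fixed
    reference frequencies makes F invariant to duplicating samples.
    """
    g = np.asarray(genotypes, dtype=float)
    obs = g != MISSING
    if not obs.any():
        raise ValueError("no observed genotypes")
    gm = np.where(obs, g, np.nan)
    if allele_freq is not None:
        p = np.asarray(allele_freq, dtype=float)
    else:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            p = np.nanmean(gm, axis=0) / 2.0
    poly = (p > 0) & (p < 1)
    if not poly.any():
        raise ValueError("F undefined: no polymorphic variants")
    gm = gm[:, poly]
    p = p[poly]
    obs = obs[:, poly]
    het_exp = 2 * p * (1 - p)  # per-variant HWE heterozygosity
    m_obs = obs.sum(axis=1)
    o_het = np.nansum(gm == 1, axis=1)
    e_hom = (obs * (1 - het_exp)).sum(axis=1)
    o_hom = m_obs - o_het
    denom = m_obs - e_hom
    F = np.where(denom > 0, (o_hom - e_hom) / np.maximum(denom, 1e-300), np.nan)
    het = np.where(m_obs > 0, o_het / np.maximum(m_obs, 1), np.nan)
    return pd.DataFrame({"F": F, "het_rate": het})


def heterozygosity_outliers(
    genotypes: np.ndarray,
    thresholds: QCThresholds = QCThresholds(),
    allele_freq: np.ndarray | None = None,
) -> tuple[np.ndarray, pd.DataFrame]:
    """Flag samples that are outliers for both F and heterozygosity rate."""
    stats = heterozygosity_stats(genotypes, allele_freq=allele_freq)
    flags = (stats["F"] > thresholds.f_max) & (stats["het_rate"] < thresholds.het_min)
    return flags.to_numpy(), stats


def global_ancestry(
    tracts: LocalAncestryMatrix, gmap: GeneticMap | None = None
) -> np.ndarray:
    """Genome-wide ancestry proportions by cM-length-weighted dosage averaging.

    Returns samples x 3 proportions (AFR, EUR, NAM), each row summing to 1.
    Weighting by genetic length makes the average invariant to how blocks
    are segmented.  Block tiling is validated by the container.
    """
    w = tracts.blocks["cm"].to_numpy(dtype=float)
    if np.any(w < 0) or w.sum() <= 0:
        raise ValueError("blocks must carry positive total genetic length")
    props = np.tensordot(tracts.dosages / 2.0, w, axes=(1, 0)) / w.sum()
    return props


def pool_group_summaries(groups: pd.DataFrame, weight_col: str = "n") -> pd.Series:
    """Sample-size-weighted pooling of per-group summary rows.

    Given per-group rows (e.g. affected/unaffected) of means, rates or
    frequencies plus a count column, returns the pooled (total) row.  Used
    to check internal consistency of cohort description tables.
    """
    w = groups[weight_col].to_numpy(dtype=float)
    pooled = {weight_col: w.sum()}
    for col in groups.columns:
        if col == weight_col:
            continue
        pooled[col] = float(np.average(groups[col].to_numpy(dtype=float), weights=w))
    return pd.Series(pooled)


def duplicate_pairs(kinship: np.ndarray, thresholds: QCThresholds = QCThresholds()):
    """Index pairs (i < j) whose kinship marks them as duplicates."""
    k = np.asarray(kinship)
    iu, ju = np.triu_indices(k.shape[0], 1)
    sel = k[iu, ju] >= thresholds.duplicate_kinship_min
    return list(zip(iu[sel].tolist(), ju[sel].tolist()))
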