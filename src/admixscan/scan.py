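"""Admixture-mapping and SNP-association scans over a fitted null model.

The unit of admixture mapping is the admixture-LD block: a maximal genomic
interval over which every sample's local-ancestry dosage triple is constant.
The joint test scores all three ancestry dosages simultaneously; because
the triple sums to 2 its rank is 2, so the test drops one ancestry column
(EUR by convention) and the statistic is provably invariant to which is
dropped.  Single-ancestry tests give 1-df p-values, with odds ratios from
Wald refits of the mixed model.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from admixscan.mixedmodel import NullModelFit, estimate_effect, fit_null
from admixscan.sim.config import ANCESTRY_LABELS, EUR
from admixscan.sim.tracts import LocalAncestryMatrix

logger = logging.getLogger(__name__)

#: Scan-wide significance conventions for the two modes.
ADMIXTURE_SIGNIFICANT = 5e-5
ADMIXTURE_SUGGESTIVE = 1e-3
ASSOCIATION_SIGNIFICANT = 5e-8


def define_blocks(tracts: LocalAncestryMatrix) -> pd.DataFrame:
    """Maximal intervals of sample-wide constant ancestry dosage.

    Adjacent stored blocks whose dosage columns agree for every sample are
    merged; boundaries are exactly the union of observed switch points.
    Returns a block table (chrom, start, end, cm, members) where ``members``
    lists the indices of the stored blocks merged into each test block.
    """
    d = tracts.dosages
    blocks = tracts.blocks
    chrom_codes = pd.factorize(blocks["chrom"])[0]
    B = len(blocks)
    new_block = np.ones(B, dtype=bool)
    if B > 1:
        same = (d[:, 1:, :] == d[:, :-1, :]).all(axis=(0, 2))
        new_block[1:] = (~same) | (chrom_codes[1:] != chrom_codes[:-1])
    starts = np.flatnonzero(new_block)
    ends = np.append(starts[1:], B)
    rows = []
    for a, b in zip(starts, ends):
        rows.append(
            {
                "chrom": blocks["chrom"].iloc[a],
                "start": int(blocks["start"].iloc[a]),
                "end": int(blocks["end"].iloc[b - 1]),
                "cm": float(blocks["cm"].iloc[a:b].sum()),
                "members": list(range(a, b)),
            }
        )
    return pd.DataFrame(rows)


def joint_ancestry_test(null: NullModelFit, block_dosages: np.ndarray):
    """2-df score test of all three ancestry dosages at one block.

    ``block_dosages`` is samples x 3 with rows summing to 2.  The EUR column
    is dropped for the test; the sum constraint makes the statistic
    invariant to that choice.
    """
    d = np.asarray(block_dosages, dtype=float)
    if d.ndim != 2 or d.shape[1] != 3:
        raise ValueError("block dosages must be samples x 3")
    if not np.allclose(d.sum(axis=1), 2.0):
        raise ValueError("dosage rows must sum to 2")
    S = d[:, [k for k in range(3) if k != EUR]]
    return null.score_test(S)


def single_ancestry_test(
    null: NullModelFit,
    dosage: np.ndarray,
    grm: np.ndarray | None = None,
    estimate_or: bool = True,
):
    """1-df score test of one ancestry's dosage, plus an optional Wald OR.

    The OR and its 95% CI come from refitting the mixed model with the
    dosage as an extra fixed effect.
    """
    dosage = np.asarray(dosage, dtype=float)
    score = null.score_test(dosage)
    effect = None
    if estimate_or:
        if np.std(dosage) == 0:
            raise ValueError("dosage is constant; effect not estimable")
        effect = estimate_effect(null.y, null.X, dosage, grm,
                                 sigma2_init=max(null.sigma2_g, 1e-4))
    return score, effect


def snp_score_test(
    null: NullModelFit,
    dosage: np.ndarray,
    grm: np.ndarray | None = None,
    condition_on: np.ndarray | None = None,
    estimate_or: bool = False,
):
    """Score test of a SNP dosage, optionally conditional on other SNPs.

    Missing dosages (coded < 0) are mean-imputed.  With ``condition_on``
    (samples x k dosages) the null is refit including those dosages as fixed
    effects before scoring; conditioning dosages collinear with the null
    covariates are rejected.
    """
    d = np.asarray(dosage, dtype=float).copy()
    miss = d < 0
    if miss.any():
        d[miss] = d[~miss].mean()
        logger.info("mean-imputed %d missing dosages", int(miss.sum()))
    base = null
    if condition_on is not None and np.size(condition_on):
        C = np.atleast_2d(np.asarray(condition_on, dtype=float).T).T
        C = C.copy()
        for j in range(C.shape[1]):
            mj = C[:, j] < 0
            if mj.any():
                C[mj, j] = C[~mj, j].mean()
        Xc = np.column_stack([null.X, C])
        if np.linalg.matrix_rank(Xc) < Xc.shape[1]:
            raise ValueError("conditioning SNPs collinear with null covariates")
        base = fit_null(null.y, Xc, grm, check_psd=False)
    score = base.score_test(d)
    effect = None
    if estimate_or and np.std(d) > 0:
        effect = estimate_effect(base.y, base.X, d, grm,
                                 sigma2_init=max(base.sigma2_g, 1e-4))
    return score, effect


def admixture_scan(
    tracts: LocalAncestryMatrix,
    null: NullModelFit,
    grm: np.ndarray | None = None,
    significant: float = ADMIXTURE_SIGNIFICANT,
    suggestive: float = ADMIXTURE_SUGGESTIVE,
    estimate_or: str = "auto",
    condition_on: np.ndarray | None = None,
) -> pd.DataFrame:
    """Joint and single-ancestry tests for every admixture-LD block.

    ``estimate_or``: 'auto' refits ORs for the driving ancestry of blocks
    reaching the suggestive threshold; 'all' refits every block (slow);
    'none' skips refits.  With ``condition_on`` (samples x k SNP dosages)
    the null is refit with those dosages as fixed effects first, giving
    conditional admixture mapping.  Results are ordered by position.
    """
    if condition_on is not None and np.size(condition_on):
        C = np.atleast_2d(np.asarray(condition_on, dtype=float).T).T
        Xc = np.column_stack([null.X, C])
        if np.linalg.matrix_rank(Xc) < Xc.shape[1]:
            raise ValueError("conditioning SNPs collinear with null covariates")
        null = fit_null(null.y, Xc, grm, check_psd=False)
    blocks = define_blocks(tracts)
    d = tracts.dosages
    rows = []
    for bi, row in blocks.iterrows():
        dose3 = d[:, row["members"][0], :].astype(float)
        joint = joint_ancestry_test(null, dose3)
        rec = {
            "chrom": row["chrom"],
            "start": row["start"],
            "end": row["end"],
            "test_type": "admixture",
            "joint_stat": joint.stat,
            "joint_df": joint.df,
            "p": joint.p,
        }
        best_anc, best_p = None, np.inf
        for k, lab in enumerate(ANCESTRY_LABELS):
            sp = null.score_test(dose3[:, k])
            rec[f"p_{lab.lower()}"] = sp.p
            if sp.p < best_p and np.std(dose3[:, k]) > 0:
                best_anc, best_p = k, sp.p
        rec["driving_ancestry"] = ANCESTRY_LABELS[best_anc] if best_anc is not None else ""
        want_or = estimate_or == "all" or (
            estimate_or == "auto" and joint.p < suggestive and best_anc is not None
        )
        if want_or:
            eff = estimate_effect(null.y, null.X, dose3[:, best_anc], grm,
                                  sigma2_init=max(null.sigma2_g, 1e-4))
            rec.update(odds_ratio=eff.odds_ratio, ci_low=eff.ci_low, ci_high=eff.ci_high)
        else:
            rec.update(odds_ratio=np.nan, ci_low=np.nan, ci_high=np.nan)
        rows.append(rec)
    out = pd.DataFrame(rows)
    out["significant"] = out["p"] < significant
    out["suggestive"] = (out["p"] < suggestive) & ~out["significant"]
    return out.sort_values(["chrom", "start"], kind="stable", ignore_index=True)


def association_scan(
    genotypes: np.ndarray,
    variants: pd.DataFrame,
    null: NullModelFit,
    grm: np.ndarray | None = None,
    significant: float = ASSOCIATION_SIGNIFICANT,
    suggestive: float = ADMIXTURE_SUGGESTIVE,
    condition_on: np.ndarray | None = None,
) -> pd.DataFrame:
    """Per-SNP score tests; empty variant sets return an empty table."""
    if len(variants) == 0:
        return pd.DataFrame(
            columns=["chrom", "pos", "id", "test_type", "p", "significant", "suggestive"]
        )
    base = null
    if condition_on is not None and np.size(condition_on):
        # refit the null once with the conditioning dosages, reuse across SNPs
        C = np.atleast_2d(np.asarray(condition_on, dtype=float).T).T
        Xc = np.column_stack([null.X, C])
        if np.linalg.matrix_rank(Xc) < Xc.shape[1]:
            raise ValueError("conditioning SNPs collinear with null covariates")
        base = fit_null(null.y, Xc, grm, check_psd=False)
    rows = []
    for j in range(genotypes.shape[1]):
        d = genotypes[:, j].astype(float)
        miss = d < 0
        if miss.any():
            d[miss] = d[~miss].mean() if (~miss).any() else 0.0
        sp = base.score_test(d)
        rows.append(
            {
                "chrom": variants["chrom"].iloc[j],
                "pos": int(variants["pos"].iloc[j]),
                "id": variants["id"].iloc[j],
                "test_type": "association",
                "p": sp.p,
            }
        )
    out = pd.DataFrame(rows)
    out["significant"] = out["p"] < significant
    out["suggestive"] = (out["p"] < suggestive) & ~out["significant"]
    return out.sort_values(["chrom", "pos"], kind="stable", ignore_index=True)


def lead_snps_per_block(
    assoc: pd.DataFrame, admix: pd.DataFrame
) -> pd.DataFrame:
    """Attach the smallest-p SNP within each block interval to the block table."""
    admix = admix.copy()
    leads = []
    for _, b in admix.iterrows():
        sel = (
            (assoc["chrom"] == b["chrom"])
            & (assoc["pos"] >= b["start"])
            & (assoc["pos"] < b["end"])
        )
        if sel.any():
            sub = assoc[sel]
            leads.append(sub.loc[sub["p"].idxmin(), "id"])
        else:
            leads.append(None)
    admix["lead_snp"] = leads
    return admix


def manhattan_plot(results: pd.DataFrame, path, significant: float, suggestive: float):
    """Plain Manhattan plot (−log10 p by genome position) written to ``path``."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(10, 3.5))
    offset = 0
    xt, xl = [], []
    pos_col = "pos" if "pos" in results else "start"
    for i, (chrom, sub) in enumerate(results.groupby("chrom", sort=False)):
        x = sub[pos_col].to_numpy() + offset
        ax.scatter(x, -np.log10(np.clip(sub["p"], 1e-300, 1)), s=6,
                   color="C0" if i % 2 == 0 else "C1")
        xt.append(offset + sub[pos_col].max() / 2)
        xl.append(str(chrom))
        offset += sub[pos_col].max()
    ax.axhline(-np.log10(significant), color="red", lw=0.8)
    ax.axhline(-np.log10(suggestive), color="blue", lw=0.8)
    ax.set_xticks(xt, xl, rotation=90, fontsize=6)
    ax.set_ylabel("-log10 p")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
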