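"""Genotype simulation conditional on haplotype-level local ancestry.

Ancestral allele frequencies default to Balding-Nichols draws: each variant
has a shared ancestral frequency p and each population's frequency is drawn
from Beta(p(1-F)/F, (1-p)(1-F)/F) with per-population differentiation F.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from admixscan.sim.config import SimConfig
from admixscan.sim.tracts import LocalAncestryMatrix


def balding_nichols_freqs(
    n_variants: int,
    fst: tuple[float, float, float],
    rng: np.random.Generator,
    anc_freq_range: tuple[float, float] = (0.1, 0.9),
) -> np.ndarray:
    """Per-population allele frequencies (variants x 3), clipped to (0.01, 0.99)."""
    p = rng.uniform(*anc_freq_range, size=n_variants)
    out = np.empty((n_variants, 3))
    for k, F in enumerate(fst):
        if F <= 0:
            out[:, k] = p
        else:
            a = p * (1 - F) / F
            b = (1 - p) * (1 - F) / F
            out[:, k] = rng.beta(a, b)
    return np.clip(out, 0.01, 0.99)


def variant_table(config: SimConfig, tracts: LocalAncestryMatrix) -> pd.DataFrame:
    """Evenly spaced biallelic variants per chromosome, inside block bounds."""
    rows = []
    for chrom, sub in tracts.blocks.groupby("chrom", sort=False):
        lo = int(sub["start"].min())
        hi = int(sub["end"].max()) - 1
        m = config.n_variants_per_chrom
        if m == 0:
            continue
        pos = np.linspace(lo, hi, m).round().astype(np.int64)
        pos = np.unique(pos)
        rows.append(pd.DataFrame({"chrom": chrom, "pos": pos}))
    if not rows:
        return pd.DataFrame(columns=["chrom", "pos", "id", "ref", "alt"])
    var = pd.concat(rows, ignore_index=True)
    var["id"] = [f"rs{i + 1:06d}" for i in range(len(var))]
    var["ref"] = "A"
    var["alt"] = "G"
    return var[["chrom", "pos", "id", "ref", "alt"]]


def simulate_genotypes(
    tracts: LocalAncestryMatrix,
    config: SimConfig,
    rng: np.random.Generator | int | None = None,
    variants: pd.DataFrame | None = None,
) -> tuple[np.ndarray, pd.DataFrame, np.ndarray]:
    """Draw haplotype alleles Bernoulli(freq of the carrying haplotype's ancestry).

    Returns ``(genotypes, variants, hap_alleles)`` where genotypes is
    samples x variants in {0,1,2} and hap_alleles is samples x variants x 2.
    Every variant must fall inside a block interval.
    """
    if tracts.hap_anc is None:
        raise ValueError("genotype simulation requires haplotype-level ancestry")
    rng = np.random.default_rng(rng)
    if variants is None:
        variants = variant_table(config, tracts)
    m = len(variants)
    if config.ancestral_allele_freqs is not None:
        freqs = np.asarray(config.ancestral_allele_freqs, dtype=float)
        if len(freqs) != m:
            raise ValueError("ancestral_allele_freqs rows must match variant count")
    else:
        freqs = balding_nichols_freqs(m, config.fst, rng)

    # map each variant to its containing block
    block_idx = np.empty(m, dtype=np.int64)
    for chrom, sub in tracts.blocks.groupby("chrom", sort=False):
        sel = variants["chrom"] == chrom
        if not sel.any():
            continue
        pos = variants.loc[sel, "pos"].to_numpy()
        starts = sub["start"].to_numpy()
        ends = sub["end"].to_numpy()
        j = np.searchsorted(starts, pos, side="right") - 1
        if np.any(j < 0) or np.any(pos >= ends[np.clip(j, 0, None)]):
            raise ValueError("variant outside any local-ancestry block")
        block_idx[sel.to_numpy()] = sub.index.to_numpy()[j]

    n = tracts.n_samples
    hap_alleles = np.empty((n, m, 2), dtype=np.int8)
    anc = tracts.hap_anc[:, block_idx, :]  # (n, m, 2)
    p = freqs[np.arange(m)[None, :, None], anc]  # (n, m, 2)
    hap_alleles[:] = rng.random((n, m, 2)) < p
    genotypes = hap_alleles.sum(axis=2).astype(np.int8)
    variants = variants.copy()
    variants["block"] = block_idx
    variants.attrs["allele_freqs"] = freqs
    return genotypes, variants, hap_alleles
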