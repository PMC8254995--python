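"""Embed known relative pairs (parent-offspring, duplicates) into a cohort.

An offspring's first haplotype is replaced by a meiosis product of the
designated parent's two haplotypes, with crossovers at rate 1 per Morgan;
its second haplotype keeps its original population draw, standing in for
the transmission of an unobserved, unrelated second parent.  Expected
kinship for the modified pair is 0.25 (parent-offspring) or 0.5 (duplicate).
"""

from __future__ import annotations

import numpy as np

from admixscan.sim.config import GeneticMap, RelatednessSpec


def _meiosis_chooser(
    rng: np.random.Generator, gmap: GeneticMap, query_cm: dict[str, np.ndarray]
) -> dict[str, np.ndarray]:
    """One crossover realization per chromosome, evaluated at query cM points."""
    out = {}
    for chrom, q in query_cm.items():
        L = gmap.length_cm(chrom)
        k = rng.poisson(L / 100.0)
        xo = np.sort(rng.uniform(0.0, L, size=k))
        start = rng.integers(2)
        out[chrom] = ((start + np.searchsorted(xo, q, side="right")) % 2).astype(np.int8)
    return out


def add_relatedness(cohort, spec: RelatednessSpec, rng: np.random.Generator | int | None = None):
    """Return a cohort with the requested relative pairs embedded.

    Samples are consumed from the end of the cohort: each pair designates one
    untouched 'source' sample and one rewritten sample.  Truth kinship for
    every embedded pair is recorded in ``cohort.truth['kinship_pairs']``.
    """
    if spec.n_pairs == 0:
        return cohort
    n = cohort.n_samples
    if spec.n_pairs * 2 > n:
        raise ValueError("each relative pair needs two cohort samples")
    rng = np.random.default_rng(rng)
    tracts = cohort.truth["true_tracts"]
    if tracts.hap_anc is None:
        raise ValueError("relatedness embedding requires haplotype-level ancestry")
    gmap = cohort.gmap
    hap_anc = tracts.hap_anc
    hap_alleles = cohort.truth["hap_alleles"]

    block_mid_cm: dict[str, np.ndarray] = {}
    var_cm: dict[str, np.ndarray] = {}
    block_pos: dict[str, np.ndarray] = {}
    var_pos: dict[str, np.ndarray] = {}
    for chrom, sub in tracts.blocks.groupby("chrom", sort=False):
        mid = 0.5 * (sub["start"].to_numpy() + sub["end"].to_numpy() - 1)
        block_mid_cm[chrom] = gmap.bp_to_cm(chrom, mid)
        block_pos[chrom] = sub.index.to_numpy()
    for chrom in tracts.blocks["chrom"].unique():
        sel = (cohort.variants["chrom"] == chrom).to_numpy()
        var_pos[chrom] = np.flatnonzero(sel)
        var_cm[chrom] = gmap.bp_to_cm(chrom, cohort.variants.loc[sel, "pos"].to_numpy())

    pairs = []
    copy_sources = {}
    next_victim = n - 1
    next_source = 0
    for kind, count in (
        ("parent_offspring", spec.n_parent_offspring),
        ("duplicate", spec.n_duplicate),
    ):
        for _ in range(count):
            src, dst = next_source, next_victim
            next_source += 1
            next_victim -= 1
            if kind == "duplicate":
                hap_anc[dst] = hap_anc[src]
                hap_alleles[dst] = hap_alleles[src]
                pairs.append((cohort.sample_ids[src], cohort.sample_ids[dst], 0.5, kind))
            else:
                queries = {c: np.concatenate([block_mid_cm[c], var_cm[c]]) for c in block_mid_cm}
                chooser = _meiosis_chooser(rng, gmap, queries)
                var_source = np.empty(cohort.n_variants, dtype=np.int8)
                for c in block_mid_cm:
                    nb = len(block_mid_cm[c])
                    ch = chooser[c]
                    hap_anc[dst, block_pos[c], 0] = hap_anc[src, block_pos[c], ch[:nb]]
                    hap_alleles[dst, var_pos[c], 0] = hap_alleles[src, var_pos[c], ch[nb:]]
                    var_source[var_pos[c]] = ch[nb:]
                copy_sources[cohort.sample_ids[dst]] = var_source
                pairs.append((cohort.sample_ids[src], cohort.sample_ids[dst], 0.25, kind))

    cohort.genotypes = hap_alleles.sum(axis=2).astype(np.int8)
    tracts._dosages = None  # force dosage recompute from modified hap_anc
    cohort.truth["kinship_pairs"] = pairs
    cohort.truth["copy_sources"] = copy_sources
    return cohort
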