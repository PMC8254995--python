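"""Readers and writers for the pipeline's interchange formats.

Formats: minimal VCF v4.2 (GT only, phased when haplotypes are known), a
local-ancestry long TSV (``#chrom start end sample hap ancestry``) plus an
msp-style dosage matrix, phenotype/covariate TSV, GRM as long TSV or
binary matrix with an id sidecar, and truth/report JSON.  All positions are
1-based; intervals are half-open [start, end).
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from admixscan.relatedness import GRM
from admixscan.sim.config import ANCESTRY_LABELS, GeneticMap
from admixscan.sim.tracts import LocalAncestryMatrix

logger = logging.getLogger(__name__)

_ANC_CODE = {lab: k for k, lab in enumerate(ANCESTRY_LABELS)}


# ---------------------------------------------------------------- VCF

def write_vcf(path, genotypes, variants, sample_ids, hap_alleles=None) -> None:
    """Minimal VCF v4.2 with GT only; phased (a|b) when haplotypes given."""
    path = Path(path)
    with path.open("w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        for chrom in pd.unique(variants["chrom"]):
            fh.write(f"##contig=<ID={chrom}>\n")
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t")
        fh.write("\t".join(sample_ids) + "\n")
        for j, (_, v) in enumerate(variants.iterrows()):
            gts = []
            for i in range(len(sample_ids)):
                if hap_alleles is not None:
                    a, b = hap_alleles[i, j]
                    gts.append(f"{a}|{b}" if a >= 0 and b >= 0 else ".|.")
                else:
                    g = genotypes[i, j]
                    gts.append("./." if g < 0 else ("0/0", "0/1", "1/1")[g])
            fh.write(
                f"{v['chrom']}\t{v['pos']}\t{v['id']}\t{v['ref']}\t{v['alt']}"
                f"\t.\t.\t.\tGT\t" + "\t".join(gts) + "\n"
            )


def read_vcf(path):
    """Parse a VCF into genotypes {0,1,2,-1}, a variant table, and haplotypes.

    Multi-allelic records are skipped (count logged).  Phase is retained:
    the returned ``hap_alleles`` (samples x variants x 2, -1 = missing) is
    valid wherever calls were phased.  A malformed header is rejected with
    its line number.
    """
    from cyvcf2 import VCF

    path = Path(path)
    with path.open() as fh:
        first = fh.readline()
        if not first.startswith("##fileformat"):
            raise ValueError(f"{path}: line 1: missing ##fileformat header")
        for ln, line in enumerate(fh, start=2):
            if line.startswith("#CHROM"):
                break
            if not line.startswith("##"):
                raise ValueError(f"{path}: line {ln}: malformed header line")
        else:
            raise ValueError(f"{path}: missing #CHROM header line")
    vcf = VCF(str(path))
    sample_ids = list(vcf.samples)
    rows, genos, haps, phased = [], [], [], []
    n_multi = 0
    for rec in vcf:
        if len(rec.ALT) != 1:
            n_multi += 1
            continue
        rows.append(
            {"chrom": rec.CHROM, "pos": rec.POS, "id": rec.ID or ".",
             "ref": rec.REF, "alt": rec.ALT[0]}
        )
        gt = np.array(rec.genotypes, dtype=int)  # (n, 3): a0, a1, phased
        a = gt[:, :2]
        a = np.where(a < 0, -1, a)
        haps.append(a)
        genos.append(np.where((a < 0).any(axis=1), -1, a.clip(0).sum(axis=1)))
        phased.append(gt[:, 2].astype(bool))
    if n_multi:
        logger.info("skipped %d multi-allelic records", n_multi)
    variants = pd.DataFrame(rows, columns=["chrom", "pos", "id", "ref", "alt"])
    genotypes = (
        np.array(genos, dtype=np.int8).T if genos else np.zeros((len(sample_ids), 0), np.int8)
    )
    hap_alleles = (
        np.array(haps, dtype=np.int8).transpose(1, 0, 2)
        if haps
        else np.zeros((len(sample_ids), 0, 2), np.int8)
    )
    phased = np.array(phased, dtype=bool).T if phased else np.zeros((len(sample_ids), 0), bool)
    return genotypes, variants, sample_ids, hap_alleles, phased


# ------------------------------------------------- local ancestry TSV

def write_local_ancestry(path, tracts: LocalAncestryMatrix) -> None:
    """Long-format haplotype ancestry TSV: #chrom start end sample hap ancestry."""
    if tracts.hap_anc is None:
        raise ValueError("long-format writer requires haplotype-level ancestry")
    with Path(path).open("w") as fh:
        fh.write("#chrom\tstart\tend\tsample\thap\tancestry\n")
        blocks = tracts.blocks
        for b in range(tracts.n_blocks):
            chrom = blocks["chrom"].iloc[b]
            start = blocks["start"].iloc[b]
            end = blocks["end"].iloc[b]
            for i, sid in enumerate(tracts.sample_ids):
                for h in range(2):
                    anc = ANCESTRY_LABELS[tracts.hap_anc[i, b, h]]
                    fh.write(f"{chrom}\t{start}\t{end}\t{sid}\t{h}\t{anc}\n")


def write_la_dosages(path, tracts: LocalAncestryMatrix) -> None:
    """msp-style dosage matrix: one row per block, 3 columns per sample."""
    cols = {}
    for k, lab in enumerate(ANCESTRY_LABELS):
        for i, sid in enumerate(tracts.sample_ids):
            cols[f"{sid}.{lab}"] = tracts.dosages[:, :, k][i]
    df = pd.DataFrame(
        {"chrom": tracts.blocks["chrom"], "start": tracts.blocks["start"],
         "end": tracts.blocks["end"], **cols}
    )
    with Path(path).open("w") as fh:
        fh.write("#" + "\t".join(df.columns) + "\n")
        df.to_csv(fh, sep="\t", header=False, index=False)


def read_local_ancestry(path, gmap: GeneticMap | None = None) -> LocalAncestryMatrix:
    """Read the long-format ancestry TSV back into a LocalAncestryMatrix.

    Validates the dosage-sum invariant (every sample-block triple sums to 2,
    i.e. exactly two haplotype rows) and interval tiling; violations are
    rejected with the offending row or interval.  Without a genetic map,
    block cM lengths default to 1 cM/Mb.
    """
    df = pd.read_csv(path, sep="\t")
    df.columns = [c.lstrip("#") for c in df.columns]
    need = {"chrom", "start", "end", "sample", "hap", "ancestry"}
    if not need <= set(df.columns):
        raise ValueError(f"local-ancestry file missing columns {need - set(df.columns)}")
    samples = list(pd.unique(df["sample"]))
    blocks = (
        df[["chrom", "start", "end"]]
        .drop_duplicates()
        .reset_index(drop=True)
    )
    for chrom, sub in blocks.groupby("chrom", sort=False):
        s = sub.sort_values("start")
        gaps = s["start"].to_numpy()[1:] != s["end"].to_numpy()[:-1]
        if gaps.any():
            bad = s.iloc[1:][gaps].iloc[0]
            raise ValueError(
                f"interval gap on {chrom} before position {int(bad['start'])}"
            )
    blocks = blocks.sort_values(["chrom", "start"], kind="stable").reset_index(drop=True)
    key = blocks["chrom"].astype(str) + ":" + blocks["start"].astype(str)
    block_of = {k: i for i, k in enumerate(key)}
    samp_of = {s: i for i, s in enumerate(samples)}
    b_idx = (df["chrom"].astype(str) + ":" + df["start"].astype(str)).map(block_of).to_numpy()
    i_idx = df["sample"].map(samp_of).to_numpy()
    h_idx = df["hap"].to_numpy()
    if not np.isin(h_idx, [0, 1]).all():
        bad = int(np.flatnonzero(~np.isin(h_idx, [0, 1]))[0]) + 2
        raise ValueError(f"row {bad}: invalid haplotype index")
    flat = (i_idx * len(blocks) + b_idx) * 2 + h_idx
    uniq, counts = np.unique(flat, return_counts=True)
    if (counts > 1).any():
        first_dup = uniq[counts > 1][0]
        bad = int(np.flatnonzero(flat == first_dup)[1]) + 2
        raise ValueError(f"row {bad}: duplicate haplotype entry")
    anc_codes = df["ancestry"].map(_ANC_CODE)
    if anc_codes.isna().any():
        bad = int(np.flatnonzero(anc_codes.isna().to_numpy())[0]) + 2
        raise ValueError(f"row {bad}: unknown ancestry label")
    hap_anc = np.full((len(samples), len(blocks), 2), -1, dtype=np.int8)
    hap_anc[i_idx, b_idx, h_idx] = anc_codes.to_numpy(dtype=np.int8)
    if (hap_anc < 0).any():
        i, b, h = np.argwhere(hap_anc < 0)[0]
        raise ValueError(
            f"sample {samples[i]} block {b}: dosage triple does not sum to 2 "
            "(missing haplotype entry)"
        )
    if gmap is not None:
        cm = [
            gmap.bp_to_cm(c, np.array([e], dtype=float))[0]
            - gmap.bp_to_cm(c, np.array([s], dtype=float))[0]
            for c, s, e in zip(blocks["chrom"], blocks["start"], blocks["end"])
        ]
        blocks["cm"] = cm
    else:
        blocks["cm"] = (blocks["end"] - blocks["start"]) / 1e6
    return LocalAncestryMatrix(sample_ids=samples, blocks=blocks, hap_anc=hap_anc)


# ------------------------------------------------- phenotype / GRM / JSON

def write_phenotype(path, sample_ids, phenotype, covariates: pd.DataFrame) -> None:
    df = pd.DataFrame({"sample": sample_ids, "status": phenotype})
    for c in covariates.columns:
        df[c] = covariates[c].to_numpy()
    with Path(path).open("w") as fh:
        fh.write("#" + "\t".join(df.columns) + "\n")
        df.to_csv(fh, sep="\t", header=False, index=False)


def read_phenotype(path):
    df = pd.read_csv(path, sep="\t")
    df.columns = [c.lstrip("#") for c in df.columns]
    pheno = df["status"].to_numpy(np.int8)
    cov = df.drop(columns=["sample", "status"])
    return list(df["sample"].astype(str)), pheno, cov


def write_grm_tsv(path, grm: GRM) -> None:
    """Long-format GRM: id1, id2, value for the upper triangle incl. diagonal."""
    ids = grm.sample_ids
    with Path(path).open("w") as fh:
        fh.write("#id1\tid2\tvalue\n")
        n = len(ids)
        for i in range(n):
            for j in range(i, n):
                fh.write(f"{ids[i]}\t{ids[j]}\t{grm.values[i, j]:.8g}\n")


def read_grm_tsv(path) -> GRM:
    df = pd.read_csv(path, sep="\t")
    df.columns = [c.lstrip("#") for c in df.columns]
    ids = list(pd.unique(pd.concat([df["id1"].astype(str), df["id2"].astype(str)])))
    idx = {s: i for i, s in enumerate(ids)}
    n = len(ids)
    v = np.zeros((n, n))
    for row in df.itertuples(index=False):
        i, j = idx[str(row.id1)], idx[str(row.id2)]
        v[i, j] = v[j, i] = row.value
    return GRM(sample_ids=ids, values=v)


def write_grm_binary(prefix, grm: GRM) -> None:
    """float64 row-major matrix at <prefix>.grm.bin with ids at <prefix>.grm.ids."""
    prefix = Path(prefix)
    grm.values.astype(np.float64).tofile(f"{prefix}.grm.bin")
    Path(f"{prefix}.grm.ids").write_text("\n".join(grm.sample_ids) + "\n")


def read_grm_binary(prefix) -> GRM:
    prefix = Path(prefix)
    ids = Path(f"{prefix}.grm.ids").read_text().split()
    n = len(ids)
    v = np.fromfile(f"{prefix}.grm.bin", dtype=np.float64).reshape(n, n)
    return GRM(sample_ids=ids, values=v)


def write_json(path, obj) -> None:
    def default(o):
        if isinstance(o, (np.integer,)):
            return int(o)
        if isinstance(o, (np.floating,)):
            return float(o)
        if isinstance(o, np.ndarray):
            return o.tolist()
        raise TypeError(f"not serializable: {type(o)}")

    Path(path).write_text(json.dumps(obj, indent=2, default=default) + "\n")
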