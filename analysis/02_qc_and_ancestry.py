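"""QC the simulated cohort and summarize global ancestry.

Applies the missingness filters and heterozygosity-outlier screen, then
recovers per-sample global ancestry by cM-weighted averaging of local
dosages, writing the QC report and ancestry summary under results/qc/.
"""

from pathlib import Path

import numpy as np

from admixscan import io as aio
from admixscan.qc import (
    QCThresholds,
    filter_missingness,
    global_ancestry,
    heterozygosity_outliers,
)

ROOT = Path(__file__).resolve().parents[1] / "results"


def main() -> None:
    out = ROOT / "qc"
    out.mkdir(parents=True, exist_ok=True)
    genotypes, variants, sample_ids, hap, phased = aio.read_vcf(ROOT / "cohort" / "genotypes.vcf")
    thr = QCThresholds()
    filtered, report = filter_missingness(genotypes, thr)
    flags, het = heterozygosity_outliers(filtered, thr)
    print(f"variants {report.n_variants_before} -> {report.n_variants_after}, "
          f"samples {report.n_samples_before} -> {report.n_samples_after}")
    print(f"heterozygosity outliers flagged: {int(flags.sum())} "
          f"(mean F {het['F'].mean():.4f}, mean het {het['het_rate'].mean():.3f})")
    aio.write_json(out / "qc_report.json", report.to_dict())

    # global ancestry from the dosage matrix written by step 01
    import pandas as pd

    dos = pd.read_csv(ROOT / "cohort" / "local_ancestry_dosages.tsv", sep="\t")
    dos.columns = [c.lstrip("#") for c in dos.columns]
    anc_cols = [c for c in dos.columns if "." in c]
    samples = sorted({c.rsplit(".", 1)[0] for c in anc_cols})
    w = ((dos["end"] - dos["start"]) / 1e6).to_numpy()
    props = np.zeros((len(samples), 3))
    for i, s in enumerate(samples):
        for k, lab in enumerate(("AFR", "EUR", "NAM")):
            props[i, k] = np.average(dos[f"{s}.{lab}"] / 2.0, weights=w)
    mean = props.mean(axis=0)
    se = props.std(axis=0, ddof=1) / np.sqrt(len(samples))
    print("global ancestry means (AFR, EUR, NAM):",
          np.round(mean, 4), "+/-", np.round(2 * se, 4))
    np.savetxt(out / "global_ancestry.tsv", props, delimiter="\t",
               header="afr\teur\tnam", comments="#")
    print(f"written to {out}")


if __name__ == "__main__":
    main()
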