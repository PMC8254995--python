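"""Run configuration and the staged end-to-end pipeline."""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from admixscan import io as aio
from admixscan import qc as aqc
from admixscan.mixedmodel import build_design, fit_null
from admixscan.multtest import effective_tests_for_scan, regional_effective_tests
from admixscan.relatedness import GRM, recursive_grm
from admixscan.scan import (
    ADMIXTURE_SIGNIFICANT,
    ADMIXTURE_SUGGESTIVE,
    ASSOCIATION_SIGNIFICANT,
    admixture_scan,
    association_scan,
    lead_snps_per_block,
    manhattan_plot,
)
from admixscan.sim import PhenoModel, RelatednessSpec, SimConfig, simulate_cohort

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Serializable description of one pipeline run.

    Unknown keys in a loaded YAML are rejected with a message; a
    save -> load round trip reproduces the config exactly.
    """

    out_dir: str = "results"
    seed: int = 0
    vcf: str | None = None
    local_ancestry: str | None = None
    phenotype: str | None = None
    grm: str | None = None
    stages: list = field(
        default_factory=lambda: ["simulate", "qc", "grm", "admixmap", "assoc"]
    )
    simulate: dict = field(default_factory=dict)  # SimConfig overrides
    qc_thresholds: dict = field(default_factory=dict)
    grm_iterations: int = 2
    alpha: float = 0.05
    admix_significant: float = ADMIXTURE_SIGNIFICANT
    admix_suggestive: float = ADMIXTURE_SUGGESTIVE
    assoc_significant: float = ASSOCIATION_SIGNIFICANT
    condition_snps: list = field(default_factory=list)
    include_age_sex: bool = False
    coloc_a: str | None = None
    coloc_b: str | None = None
    coloc_priors: dict = field(default_factory=lambda: {"p1": 1e-4, "p2": 1e-4, "p12": 1e-5})

    @classmethod
    def load(cls, path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def save(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(dataclasses.asdict(self), sort_keys=False))

    def sim_config(self) -> SimConfig:
        kw = dict(self.simulate)
        if "pheno" in kw:
            kw["pheno"] = PhenoModel(**kw["pheno"])
        if "relatedness" in kw:
            kw["relatedness"] = RelatednessSpec(**kw["relatedness"])
        if "chrom_lengths_cm" in kw:
            kw["chrom_lengths_cm"] = tuple(kw["chrom_lengths_cm"])
        if "global_props" in kw:
            kw["global_props"] = tuple(kw["global_props"])
        kw.setdefault("seed", self.seed)
        return SimConfig(**kw)


def run_pipeline(config: RunConfig, force: bool = False) -> Path:
    """Execute the configured stages, writing results under ``out_dir``.

    Any stage failure raises with the stage name attached; outputs of
    completed stages are preserved.  Reruns with an identical config are
    bit-identical for the deterministic stages.
    """
    out = Path(config.out_dir)
    if out.exists() and any(out.iterdir()) and not force:
        raise FileExistsError(f"output directory {out} is not empty (use force)")
    out.mkdir(parents=True, exist_ok=True)
    config.save(out / "run_config.yaml")

    state: dict = {}
    for stage in config.stages:
        fn = _STAGES.get(stage)
        if fn is None:
            raise ValueError(f"unknown stage {stage!r}")
        logger.info("stage %s: starting (seed=%d)", stage, config.seed)
        try:
            fn(config, state, out)
        except Exception as e:
            raise RuntimeError(f"pipeline stage {stage!r} failed: {e}") from e
    return out


def _stage_simulate(config: RunConfig, state: dict, out: Path) -> None:
    cohort = simulate_cohort(config.sim_config())
    state["cohort"] = cohort
    aio.write_vcf(
        out / "genotypes.vcf", cohort.genotypes, cohort.variants, cohort.sample_ids,
        hap_alleles=cohort.truth["hap_alleles"],
    )
    aio.write_la_dosages(out / "local_ancestry_dosages.tsv", cohort.tracts)
    aio.write_local_ancestry(out / "local_ancestry.tsv", cohort.tracts)
    aio.write_phenotype(out / "phenotype.tsv", cohort.sample_ids, cohort.phenotype,
                        cohort.covariates)
    truth = {
        "causal_block": cohort.truth.get("causal_block"),
        "causal_snp": cohort.truth.get("causal_snp"),
        "kinship_pairs": cohort.truth.get("kinship_pairs", []),
        "seed": config.seed,
    }
    aio.write_json(out / "truth.json", truth)


def _load_inputs(config: RunConfig, state: dict) -> None:
    if "cohort" in state or "genotypes" in state:
        return
    if not (config.vcf and config.local_ancestry and config.phenotype):
        raise ValueError("vcf, local_ancestry and phenotype paths are required")
    genotypes, variants, sample_ids, hap, phased = aio.read_vcf(config.vcf)
    tracts = aio.read_local_ancestry(config.local_ancestry)
    ids, pheno, cov = aio.read_phenotype(config.phenotype)
    state.update(
        genotypes=genotypes, variants=variants, sample_ids=sample_ids,
        tracts=tracts, phenotype=pheno, covariates=cov,
    )


def _get(state: dict, key: str):
    if "cohort" in state:
        c = state["cohort"]
        return {
            "genotypes": c.genotypes, "variants": c.variants,
            "sample_ids": c.sample_ids, "tracts": c.tracts,
            "phenotype": c.phenotype, "covariates": c.covariates,
        }[key]
    return state[key]


def _stage_qc(config: RunConfig, state: dict, out: Path) -> None:
    _load_inputs(config, state)
    thr = aqc.QCThresholds(**config.qc_thresholds)
    g = _get(state, "genotypes")
    filtered, report = aqc.filter_missingness(g, thr)
    flags, het = aqc.heterozygosity_outliers(filtered, thr) if filtered.size else (
        np.array([]), pd.DataFrame())
    report.per_sample = het if len(het) else None
    report.flagged_samples = np.flatnonzero(flags).tolist()
    props = aqc.global_ancestry(_get(state, "tracts"))
    state["global_props"] = props
    state["qc_report"] = report
    aio.write_json(out / "qc_report.json", report.to_dict())
    np.savetxt(out / "global_ancestry.tsv", props, delimiter="\t",
               header="afr\teur\tnam", comments="#")


def _stage_grm(config: RunConfig, state: dict, out: Path) -> None:
    _load_inputs(config, state)
    if config.grm:
        state["grm"] = aio.read_grm_tsv(config.grm)
    else:
        grm, pcs = recursive_grm(
            _get(state, "genotypes"), iterations=config.grm_iterations,
            sample_ids=_get(state, "sample_ids"),
        )
        state["grm"] = grm
        aio.write_grm_tsv(out / "grm.tsv", grm)


def _null_fit(config: RunConfig, state: dict):
    if "null" not in state:
        if "global_props" not in state:
            state["global_props"] = aqc.global_ancestry(_get(state, "tracts"))
        X, names = build_design(
            _get(state, "covariates"), state["global_props"],
            include_age_sex=config.include_age_sex,
        )
        grm = state.get("grm")
        state["null"] = fit_null(
            _get(state, "phenotype"), X,
            grm.values if isinstance(grm, GRM) else grm,
            covariate_names=names,
        )
    return state["null"]


def _stage_admixmap(config: RunConfig, state: dict, out: Path) -> None:
    _load_inputs(config, state)
    null = _null_fit(config, state)
    tracts = _get(state, "tracts")
    eff = effective_tests_for_scan(tracts, alpha=config.alpha)
    grm = state.get("grm")
    grm_values = grm.values if isinstance(grm, GRM) else grm
    results = admixture_scan(
        tracts, null, grm_values,
        significant=config.admix_significant, suggestive=config.admix_suggestive,
    )
    state["admixmap"] = results
    results.to_csv(out / "admixmap_results.tsv", sep="\t", index=False)
    aio.write_json(
        out / "effective_tests.json",
        {
            "per_ancestry": dict(zip(("AFR", "EUR", "NAM"), eff.per_ancestry)),
            "combined": eff.combined, "alpha": eff.alpha,
            "threshold": eff.threshold,
        },
    )
    manhattan_plot(results, out / "admixmap_manhattan.png",
                   config.admix_significant, config.admix_suggestive)


def _stage_assoc(config: RunConfig, state: dict, out: Path) -> None:
    _load_inputs(config, state)
    null = _null_fit(config, state)
    grm = state.get("grm")
    grm_values = grm.values if isinstance(grm, GRM) else grm
    results = association_scan(
        _get(state, "genotypes"), _get(state, "variants"), null, grm_values,
        significant=config.assoc_significant,
    )
    g = _get(state, "genotypes")
    if g.shape[1] > 1:
        meff, sig, sug = regional_effective_tests(g, alpha=config.alpha)
        aio.write_json(out / "regional_effective_tests.json",
                       {"m_eff": meff, "significant": sig, "suggestive": sug})
    state["assoc"] = results
    results.to_csv(out / "assoc_results.tsv", sep="\t", index=False)
    if "admixmap" in state:
        leads = lead_snps_per_block(results, state["admixmap"])
        leads.to_csv(out / "admixmap_results.tsv", sep="\t", index=False)
    if len(results):
        manhattan_plot(results, out / "assoc_manhattan.png",
                       config.assoc_significant, config.admix_suggestive)


def _stage_condition(config: RunConfig, state: dict, out: Path) -> None:
    _load_inputs(config, state)
    if not config.condition_snps:
        raise ValueError("condition stage requires condition_snps")
    null = _null_fit(config, state)
    variants = _get(state, "variants")
    idx = [variants.index[variants["id"] == s][0] for s in config.condition_snps]
    C = _get(state, "genotypes")[:, idx].astype(float)
    grm = state.get("grm")
    grm_values = grm.values if isinstance(grm, GRM) else grm
    tracts = _get(state, "tracts")
    results = admixture_scan(
        tracts, null, grm_values, condition_on=C,
        significant=config.admix_significant, suggestive=config.admix_suggestive,
        estimate_or="none",
    )
    results.to_csv(out / "conditional_admixmap_results.tsv", sep="\t", index=False)
    state["conditional"] = results


def _stage_coloc(config: RunConfig, state: dict, out: Path) -> None:
    from admixscan.coloc import SummaryStats, coloc_abf, coloc_scatter, per_snp_table

    if not (config.coloc_a and config.coloc_b):
        raise ValueError("coloc stage requires coloc_a and coloc_b summary tables")
    sa = SummaryStats.from_table(pd.read_csv(config.coloc_a, sep="\t"))
    sb = SummaryStats.from_table(pd.read_csv(config.coloc_b, sep="\t"), trait_type="quant")
    res = coloc_abf(sa, sb, **config.coloc_priors)
    aio.write_json(out / "coloc.json",
                   {"pp": res.pp, "n_shared": res.n_shared, "priors": list(res.priors)})
    per_snp_table(res).to_csv(out / "coloc_per_snp.tsv", sep="\t", index=False)
    coloc_scatter(sa, sb, out / "coloc_scatter.png")


_STAGES = {
    "simulate": _stage_simulate,
    "qc": _stage_qc,
    "grm": _stage_grm,
    "admixmap": _stage_admixmap,
    "assoc": _stage_assoc,
    "condition": _stage_condition,
    "coloc": _stage_coloc,
}
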