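"""Simulation configuration: ancestry labels, genetic map, cohort parameters."""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass, field

import numpy as np

#: Fixed ancestry ordering used everywhere in the package.
AFR, EUR, NAM = 0, 1, 2
ANCESTRY_LABELS = ("AFR", "EUR", "NAM")


@dataclass(frozen=True)
class GeneticMap:
    """Piecewise-linear bp<->cM map for a set of chromosomes.

    Each chromosome carries aligned anchor arrays of 1-based base-pair
    positions (strictly increasing) and centimorgan values (non-decreasing).
    The default constructor :meth:`constant_rate` uses 1 cM/Mb.
    """

    chroms: tuple[str, ...]
    positions: tuple[np.ndarray, ...]  # bp anchors per chromosome
    cms: tuple[np.ndarray, ...]  # cM anchors per chromosome

    def __post_init__(self) -> None:
        if len(self.chroms) == 0:
            raise ValueError("genetic map must cover at least one chromosome")
        if not (len(self.chroms) == len(self.positions) == len(self.cms)):
            raise ValueError("chroms, positions, cms must align")
        for pos, cm in zip(self.positions, self.cms):
            if len(pos) != len(cm) or len(pos) < 2:
                raise ValueError("each chromosome needs >= 2 aligned anchors")
            if not np.all(np.diff(pos) > 0):
                raise ValueError("bp positions must be strictly increasing")
            if not np.all(np.diff(cm) >= 0):
                raise ValueError("cM values must be non-decreasing")

    @classmethod
    def constant_rate(
        cls, chrom_lengths_cm: tuple[float, ...], cm_per_mb: float = 1.0
    ) -> "GeneticMap":
        chroms, positions, cms = [], [], []
        for i, L in enumerate(chrom_lengths_cm):
            chroms.append(f"chr{i + 1}")
            end_bp = int(round(L / cm_per_mb * 1e6)) + 1
            positions.append(np.array([1, end_bp], dtype=np.int64))
            cms.append(np.array([0.0, L], dtype=float))
        return cls(tuple(chroms), tuple(positions), tuple(cms))

    def chrom_index(self, chrom: str) -> int:
        return self.chroms.index(chrom)

    def length_cm(self, chrom: str) -> float:
        i = self.chrom_index(chrom)
        return float(self.cms[i][-1] - self.cms[i][0])

    def total_cm(self) -> float:
        return sum(self.length_cm(c) for c in self.chroms)

    def cm_to_bp(self, chrom: str, cm: np.ndarray) -> np.ndarray:
        i = self.chrom_index(chrom)
        bp = np.interp(cm, self.cms[i], self.positions[i].astype(float))
        return np.rint(bp).astype(np.int64)

    def bp_to_cm(self, chrom: str, bp: np.ndarray) -> np.ndarray:
        i = self.chrom_index(chrom)
        return np.interp(bp, self.positions[i].astype(float), self.cms[i])


@dataclass(frozen=True)
class PhenoModel:
    """Logistic phenotype model.

    The linear predictor is

        eta = intercept
              + beta_age * (age - age_mean) + beta_sex * (sex - female_prob)
              + beta_e2 * (e2 - 2*e2_freq) + beta_e4 * (e4 - 2*e4_freq)
              + ancestry_logor * dosage(causal_ancestry at causal_block)
              + allelic_logor * genotype(causal_snp)

    Covariates are centered at their configured means so the intercept is the
    log-odds of disease for an average individual with zero causal dosage.
    """

    intercept: float = -0.17  # logit(0.458): case fraction of the target cohort
    beta_age: float = 0.0
    beta_sex: float = 0.0
    beta_e2: float = 0.0
    beta_e4: float = 0.0
    ancestry_logor: float = 0.0
    causal_block: int | None = None
    causal_ancestry: int = NAM
    allelic_logor: float = 0.0
    causal_snp: int | None = None


@dataclass(frozen=True)
class RelatednessSpec:
    """Counts of relative pairs to embed (each pair consumes two samples)."""

    n_parent_offspring: int = 0
    n_duplicate: int = 0

    @property
    def n_pairs(self) -> int:
        return self.n_parent_offspring + self.n_duplicate


@dataclass(frozen=True)
class SimConfig:
    """Parameters of the admixed-cohort generator.

    Defaults reflect the Caribbean Hispanic study population this package
    targets: global ancestry proportions 0.33 AFR / 0.58 EUR / 0.09 NAM,
    roughly ten generations since admixture, age ~ N(73.6, 9.0) truncated to
    [35, 100], 66.1% female, APOE e2/e4 allele frequencies 5.6%/20.7%.
    """

    n_samples: int = 500
    n_variants_per_chrom: int = 50
    chrom_lengths_cm: tuple[float, ...] = tuple([150.0] * 20)
    window_cm: float = 15.0  # local-ancestry observation resolution
    generations_g: float = 10.0
    global_props: tuple[float, float, float] = (0.33, 0.58, 0.09)  # AFR, EUR, NAM
    fst: tuple[float, float, float] = (0.1, 0.1, 0.1)
    ancestral_allele_freqs: np.ndarray | None = None  # variants x 3, overrides fst
    pheno: PhenoModel = field(default_factory=PhenoModel)
    relatedness: RelatednessSpec = field(default_factory=RelatednessSpec)
    la_noise_rate: float = 0.0
    age_mean: float = 73.6
    age_sd: float = 9.0
    female_prob: float = 0.661
    e2_freq: float = 0.056
    e4_freq: float = 0.207
    seed: int = 0

    def __post_init__(self) -> None:
        props = np.asarray(self.global_props, dtype=float)
        if props.shape != (3,):
            raise ValueError("global_props must have exactly three entries")
        if np.any(props < 0):
            raise ValueError("global_props must be non-negative")
        if abs(props.sum() - 1.0) > 1e-12:
            raise ValueError("global_props must sum to 1 within 1e-12")
        if not math.isfinite(self.generations_g) or self.generations_g <= 0:
            raise ValueError("generations_g must be finite and positive")
        if self.n_samples < 1 or self.n_variants_per_chrom < 0:
            raise ValueError("n_samples >= 1 and n_variants_per_chrom >= 0 required")
        if self.window_cm <= 0:
            raise ValueError("window_cm must be positive")
        if not (0.0 <= self.la_noise_rate < 1.0):
            raise ValueError("la_noise_rate must lie in [0, 1)")
        if self.ancestral_allele_freqs is not None:
            f = np.asarray(self.ancestral_allele_freqs, dtype=float)
            if f.ndim != 2 or f.shape[1] != 3:
                raise ValueError("ancestral_allele_freqs must be variants x 3")
            if np.any(f < 0) or np.any(f > 1):
                raise ValueError("allele frequencies must lie in [0, 1]")
        if self.relatedness.n_pairs * 2 > self.n_samples:
            raise ValueError("relative pairs require 2 samples each; too many requested")

    def replace(self, **kwargs) -> "SimConfig":
        return dataclasses.replace(self, **kwargs)

    def genetic_map(self) -> GeneticMap:
        return GeneticMap.constant_rate(self.chrom_lengths_cm)
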