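"""Local-ancestry tract simulation and the LocalAncestryMatrix container.

The tract model is a hybrid-isolation Markov approximation: along each
haplotype, ancestry switch points follow a Poisson process with rate g per
Morgan (g = generations since admixture) and the ancestry of each segment is
drawn independently from the global admixture proportions.  Ancestry is
*observed* on a marker-window grid (``window_cm``), mirroring the windowed
output of local-ancestry inference tools; the continuous switch process is
simulated exactly and its switch counts and segment lengths are retained in
``sim_stats`` for validation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from admixscan.sim.config import GeneticMap, SimConfig


@dataclass
class LocalAncestryMatrix:
    """Per-sample local-ancestry dosages over genome blocks.

    ``blocks`` has columns ``chrom``, ``start``, ``end`` (1-based bp,
    half-open [start, end)) and ``cm`` (genetic length).  ``hap_anc`` holds
    the ancestry code of each haplotype in each block (samples x blocks x 2);
    dosages (samples x blocks x 3, copies of each ancestry) are derived from
    it.  Matrices loaded from dosage-only files carry ``dosages`` directly.
    """

    sample_ids: list[str]
    blocks: pd.DataFrame
    hap_anc: np.ndarray | None = None
    _dosages: np.ndarray | None = None
    sim_stats: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.hap_anc is None and self._dosages is None:
            raise ValueError("need hap_anc or dosages")
        self.validate()

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @property
    def n_blocks(self) -> int:
        return len(self.blocks)

    @property
    def dosages(self) -> np.ndarray:
        if self._dosages is None:
            d = np.zeros((self.n_samples, self.n_blocks, 3), dtype=np.int8)
            for h in range(2):
                np.add.at(
                    d,
                    (
                        np.arange(self.n_samples)[:, None],
                        np.arange(self.n_blocks)[None, :],
                        self.hap_anc[:, :, h],
                    ),
                    1,
                )
            self._dosages = d
        return self._dosages

    def validate(self) -> None:
        if self.hap_anc is not None:
            n, b, two = self.hap_anc.shape
            if two != 2 or n != self.n_samples or b != self.n_blocks:
                raise ValueError("hap_anc shape inconsistent with samples/blocks")
        if self._dosages is not None and not np.all(self._dosages.sum(axis=2) == 2):
            raise ValueError("dosage triples must sum to exactly 2")
        for _, sub in self.blocks.groupby("chrom", sort=False):
            starts = sub["start"].to_numpy()
            ends = sub["end"].to_numpy()
            if np.any(ends <= starts):
                raise ValueError("blocks must have end > start")
            if np.any(starts[1:] != ends[:-1]):
                raise ValueError("blocks must tile each chromosome without gaps")

    def block_index_for(self, chrom: str, pos: int) -> int:
        """Index of the block containing 1-based position ``pos``; -1 if none."""
        sub = self.blocks[self.blocks["chrom"] == chrom]
        if sub.empty:
            return -1
        starts = sub["start"].to_numpy()
        ends = sub["end"].to_numpy()
        j = np.searchsorted(starts, pos, side="right") - 1
        if j < 0 or pos >= ends[j]:
            return -1
        return int(sub.index[j])


def _simulate_chrom_haplotypes(
    rng: np.random.Generator,
    n_hap: int,
    length_cm: float,
    g: float,
    props: np.ndarray,
    mids_cm: np.ndarray,
) -> tuple[np.ndarray, np.ndarray, list[np.ndarray]]:
    """Continuous Poisson tract process evaluated at window midpoints.

    Returns window ancestries (n_hap x n_windows), raw switch counts per
    haplotype, and the list of continuous segment lengths per haplotype (cM).
    """
    L_morgan = length_cm / 100.0
    n_sw = rng.poisson(g * L_morgan, size=n_hap)
    anc = np.empty((n_hap, len(mids_cm)), dtype=np.int8)
    seg_lengths: list[np.ndarray] = []
    for h in range(n_hap):
        k = n_sw[h]
        sw = np.sort(rng.uniform(0.0, length_cm, size=k))
        seg_anc = rng.choice(3, size=k + 1, p=props).astype(np.int8)
        idx = np.searchsorted(sw, mids_cm, side="right")
        anc[h] = seg_anc[idx]
        seg_lengths.append(np.diff(np.concatenate(([0.0], sw, [length_cm]))))
    return anc, n_sw, seg_lengths


def simulate_tracts(
    config: SimConfig,
    gmap: GeneticMap | None = None,
    rng: np.random.Generator | int | None = None,
) -> LocalAncestryMatrix:
    """Simulate local-ancestry tracts for ``config.n_samples`` diploids.

    Block intervals are the union of observed (grid-level) switch points:
    adjacent grid windows in which no haplotype changes ancestry are merged,
    so every returned block boundary is an ancestry switch point of at least
    one haplotype (or a chromosome end).
    """
    if gmap is None:
        gmap = config.genetic_map()
    if len(gmap.chroms) == 0:
        raise ValueError("empty genetic map")
    rng = np.random.default_rng(config.seed if rng is None else rng)
    props = np.asarray(config.global_props, dtype=float)
    n = config.n_samples
    n_hap = 2 * n

    all_rows = []
    hap_cols = []
    switch_counts = np.zeros(n_hap, dtype=np.int64)
    seg_lengths_all: list[np.ndarray] = []
    for chrom in gmap.chroms:
        L = gmap.length_cm(chrom)
        bounds = np.arange(0.0, L, config.window_cm)
        bounds = np.append(bounds, L)
        if len(bounds) < 2:
            bounds = np.array([0.0, L])
        mids = 0.5 * (bounds[:-1] + bounds[1:])
        anc, n_sw, segs = _simulate_chrom_haplotypes(
            rng, n_hap, L, config.generations_g, props, mids
        )
        switch_counts += n_sw
        seg_lengths_all.extend(segs)
        # merge adjacent windows with no observed switch in any haplotype
        keep = np.ones(len(mids), dtype=bool)
        keep[1:] = np.any(anc[:, 1:] != anc[:, :-1], axis=0)
        starts_cm = bounds[:-1][keep]
        ends_cm = np.append(starts_cm[1:], L)
        anc = anc[:, keep]
        start_bp = gmap.cm_to_bp(chrom, starts_cm)
        end_bp = gmap.cm_to_bp(chrom, ends_cm)
        end_bp[-1] += 1  # half-open: cover the final position
        start_bp[0] = gmap.positions[gmap.chrom_index(chrom)][0]
        all_rows.append(
            pd.DataFrame(
                {
                    "chrom": chrom,
                    "start": start_bp,
                    "end": end_bp,
                    "cm": ends_cm - starts_cm,
                }
            )
        )
        hap_cols.append(anc)

    blocks = pd.concat(all_rows, ignore_index=True)
    hap_anc = np.concatenate(hap_cols, axis=1)  # (2n, B)
    hap_anc = np.stack([hap_anc[:n], hap_anc[n:]], axis=2)  # (n, B, 2)
    sample_ids = [f"S{i:05d}" for i in range(n)]
    lam = LocalAncestryMatrix(
        sample_ids=sample_ids,
        blocks=blocks,
        hap_anc=hap_anc,
        sim_stats={
            "switch_counts": switch_counts,
            "segment_lengths_cm": np.concatenate(seg_lengths_all),
        },
    )
    return lam


def perturb_local_ancestry(
    tracts: LocalAncestryMatrix,
    la_noise_rate: float,
    rng: np.random.Generator | int | None = None,
) -> LocalAncestryMatrix:
    """Relabel whole haplotype segments at random, modeling inference error.

    Each maximal run of constant ancestry along a haplotype (within a
    chromosome) is independently relabeled, with probability
    ``la_noise_rate``, to one of the two other ancestries chosen uniformly.
    The dosage-sum invariant is preserved by construction.
    """
    if not (0.0 <= la_noise_rate < 1.0):
        raise ValueError("la_noise_rate must lie in [0, 1)")
    if tracts.hap_anc is None:
        raise ValueError("perturbation requires haplotype-level ancestry")
    rng = np.random.default_rng(rng)
    if la_noise_rate == 0.0:
        return LocalAncestryMatrix(
            sample_ids=list(tracts.sample_ids),
            blocks=tracts.blocks.copy(),
            hap_anc=tracts.hap_anc.copy(),
            sim_stats={"n_segments": 0, "n_relabeled": 0},
        )
    hap = tracts.hap_anc.copy()
    chrom_codes = pd.factorize(tracts.blocks["chrom"])[0]
    n, B, _ = hap.shape
    n_segments = 0
    n_relabeled = 0
    for s in range(n):
        for h in range(2):
            seq = hap[s, :, h]
            new_run = np.ones(B, dtype=bool)
            new_run[1:] = (seq[1:] != seq[:-1]) | (chrom_codes[1:] != chrom_codes[:-1])
            run_starts = np.flatnonzero(new_run)
            run_ends = np.append(run_starts[1:], B)
            n_segments += len(run_starts)
            flip = rng.random(len(run_starts)) < la_noise_rate
            for a, b, do in zip(run_starts, run_ends, flip):
                if do:
                    old = seq[a]
                    choices = [c for c in range(3) if c != old]
                    seq[a:b] = choices[rng.integers(2)]
                    n_relabeled += 1
            hap[s, :, h] = seq
    return LocalAncestryMatrix(
        sample_ids=list(tracts.sample_ids),
        blocks=tracts.blocks.copy(),
        hap_anc=hap,
        sim_stats={"n_segments": n_segments, "n_relabeled": n_relabeled},
    )
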