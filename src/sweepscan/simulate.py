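"""Synthetic phased haplotypes, sweeps and autozygous tracts with known truth.

The generator emulates a medium-density (~50K) SNP-array dataset for a single
sheep population so every downstream stage (QC, diversity, ROH, iHS, region
calling) has a parameter-recovery test without external data:

* **Neutral haplotypes** come from a two-pool hidden-Markov model: each SNP
  draws a population allele frequency from a U-shaped (Beta(0.5, 0.5))
  spectrum; each haplotype follows a Markov chain over two latent "parent
  pools" whose pool-specific frequencies straddle the population frequency.
  State persistence along the chromosome produces local linkage
  disequilibrium that decays with the per-adjacent-SNP switch probability.
* **Sweeps** (:func:`plant_sweep`) copy one donor haplotype over a flank
  around a focal SNP into a chosen fraction of haplotypes, with copy
  fidelity decaying linearly from 1 at the focal SNP to 0 at the flank
  edges — the long-shared-haplotype structure an iHS scan detects.
* **Autozygous tracts** (:func:`make_inbred_genotypes`) overwrite one
  parental haplotype with the other inside truth tracts, producing the long
  homozygous runs a ROH scan detects, plus optional missing calls.

All three operations are bit-reproducible from their seeds.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .containers import MISSING, GenotypeMatrix, HaplotypeSet, LocusMap
from .errors import ConfigurationError, DomainError

__all__ = [
    "SimConfig",
    "SweepTruth",
    "AutozygosityTruth",
    "simulate_neutral_haplotypes",
    "plant_sweep",
    "make_inbred_genotypes",
]


@dataclass(frozen=True)
class SimConfig:
    """Study-scale defaults: ~46K autosomal SNPs in a few hundred sheep.

    ``recombination_rate`` is a per-adjacent-SNP probability that a
    haplotype switches latent parent pool; at the default array spacing
    (~57 kb between SNPs) 0.05 gives LD decaying over roughly 1 Mb, the
    scale of array-detectable haplotype structure.
    """

    n_individuals: int = 250
    n_snps_per_chrom: int = 1767
    n_chroms: int = 26
    chrom_length: int = 100_000_000
    recombination_rate: float = 0.05
    maf_floor: float = 0.05
    #: pool divergence: pool frequencies are f +- pool_divergence*min(f, 1-f)
    pool_divergence: float = 0.8
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_individuals < 2:
            raise ConfigurationError("n_individuals must be >= 2")
        if self.n_snps_per_chrom < 1:
            raise ConfigurationError("n_snps_per_chrom must be >= 1")
        if self.n_chroms < 1:
            raise ConfigurationError("n_chroms must be >= 1")
        if self.chrom_length <= 0:
            raise ConfigurationError("chrom_length must be > 0")
        if not 0.0 <= self.recombination_rate <= 1.0:
            raise ConfigurationError("recombination_rate must lie in [0, 1]")
        if not 0.0 <= self.maf_floor <= 0.5:
            raise ConfigurationError("maf_floor must lie in [0, 0.5]")
        if not 0.0 <= self.pool_divergence <= 1.0:
            raise ConfigurationError("pool_divergence must lie in [0, 1]")
        if self.n_snps_per_chrom > self.chrom_length:
            raise ConfigurationError("n_snps_per_chrom exceeds chrom_length")


@dataclass(frozen=True)
class SweepTruth:
    """Ground truth for one planted sweep (for recovery tests)."""

    chromosome: str
    focal_position: int
    sweep_frequency: float
    flank_span: int

    def __post_init__(self) -> None:
        if not 0.0 < self.sweep_frequency < 1.0:
            raise ConfigurationError("sweep_frequency must lie in (0, 1)")
        if self.flank_span <= 0:
            raise ConfigurationError("flank_span must be > 0")


@dataclass(frozen=True)
class AutozygosityTruth:
    """Ground truth for one planted autozygous tract."""

    individual: str
    chromosome: str
    tract_start: int
    tract_end: int

    def __post_init__(self) -> None:
        if self.tract_start >= self.tract_end:
            raise ConfigurationError("tract_start must be < tract_end")

    @property
    def length(self) -> int:
        return self.tract_end - self.tract_start + 1


def _draw_positions(rng: np.random.Generator, n: int, length: int) -> np.ndarray:
    """n distinct 1-based positions, sorted; uniform over the chromosome."""
    pos: np.ndarray = np.unique(rng.integers(1, length + 1, size=2 * n))
    while pos.size < n:
        pos = np.unique(np.concatenate([pos, rng.integers(1, length + 1, size=n)]))
    return np.sort(rng.choice(pos, size=n, replace=False))


def simulate_neutral_haplotypes(config: SimConfig) -> tuple[HaplotypeSet, LocusMap]:
    """Generate neutral phased haplotypes plus their locus map.

    Guarantees each SNP's realized minor allele frequency is at least
    ``config.maf_floor`` (enforced, after the stochastic draw, by flipping
    randomly chosen majority-allele copies at deficient SNPs).
    """
    rng = np.random.default_rng(config.seed)
    n_hap = 2 * config.n_individuals
    m = config.n_snps_per_chrom

    chroms, names, positions = [], [], []
    blocks = []
    for c in range(1, config.n_chroms + 1):
        pos = _draw_positions(rng, m, config.chrom_length)
        f = rng.beta(0.5, 0.5, size=m)
        f = np.clip(f, max(config.maf_floor, 1e-3), 1 - max(config.maf_floor, 1e-3))
        delta = config.pool_divergence * np.minimum(f, 1 - f)
        f_pool = np.stack([f - delta, f + delta])  # 2 x m

        # latent pool per haplotype per SNP: Markov chain along the chromosome
        switch = rng.random((n_hap, m - 1)) < config.recombination_rate if m > 1 \
            else np.zeros((n_hap, 0), bool)
        s0 = rng.integers(0, 2, size=n_hap)
        state = (s0[:, None] + np.concatenate(
            [np.zeros((n_hap, 1), np.int64), np.cumsum(switch, axis=1)], axis=1)) % 2
        hap = (rng.random((n_hap, m)) < f_pool[state, np.arange(m)]).astype(np.uint8)

        _enforce_maf_floor(hap, config.maf_floor, rng)

        blocks.append(hap)
        chroms.append(np.full(m, str(c), dtype=object))
        names.append(np.asarray([f"snp{c}_{p}" for p in pos], dtype=object))
        positions.append(pos)

    loci = LocusMap(
        chrom=np.concatenate(chroms),
        name=np.concatenate(names),
        pos=np.concatenate(positions),
        allele_a=np.full(config.n_chroms * m, "A", dtype=object),
        allele_b=np.full(config.n_chroms * m, "B", dtype=object),
    )
    individuals = [f"ind{i:04d}" for i in range(config.n_individuals)]
    haps = HaplotypeSet(individuals, np.concatenate(blocks, axis=1))
    return haps, loci


def _enforce_maf_floor(hap: np.ndarray, floor: float, rng: np.random.Generator) -> None:
    """Flip majority-allele copies in place until every column MAF >= floor."""
    if floor <= 0:
        return
    n_hap = hap.shape[0]
    need = math.ceil(floor * n_hap)
    count1 = hap.sum(axis=0)
    for j in np.flatnonzero(np.minimum(count1, n_hap - count1) < need):
        minor = 1 if count1[j] <= n_hap - count1[j] else 0
        carriers_major = np.flatnonzero(hap[:, j] != minor)
        k = need - (n_hap - carriers_major.size)
        flip = rng.choice(carriers_major, size=k, replace=False)
        hap[flip, j] = minor


def plant_sweep(haps: HaplotypeSet, loci: LocusMap, truth: SweepTruth,
                seed: int) -> HaplotypeSet:
    """Plant one partial selective sweep; returns a new HaplotypeSet.

    A donor haplotype is chosen at random and copied over the flank
    ``[focal - flank_span, focal + flank_span]`` into exactly
    ``round(sweep_frequency * n_haplotypes)`` carrier haplotypes, with
    per-SNP copy fidelity ``1 - distance/flank_span``.  The focal column is
    recoded so the donor (derived) allele marks the carriers exactly:
    carriers get the donor allele, all other haplotypes the alternative
    allele.  Outside the focal column, non-carriers are untouched, and no
    entry outside the flank changes.
    """
    rng = np.random.default_rng(seed)
    chrom_idx = loci.chrom_indices().get(str(truth.chromosome))
    if chrom_idx is None:
        raise DomainError(f"chromosome {truth.chromosome!r} not in locus map")
    pos = loci.pos[chrom_idx]
    if not pos[0] <= truth.focal_position <= pos[-1]:
        raise DomainError(
            f"focal_position {truth.focal_position} outside mapped span "
            f"[{pos[0]}, {pos[-1]}] of chromosome {truth.chromosome}")

    focal_local = int(np.argmin(np.abs(pos - truth.focal_position)))
    focal = int(chrom_idx[focal_local])
    dist = np.abs(pos - pos[focal_local])
    flank_local = np.flatnonzero(dist <= truth.flank_span)
    fidelity = 1.0 - dist[flank_local] / truth.flank_span

    n_hap = haps.n_haplotypes
    n_carriers = int(round(truth.sweep_frequency * n_hap))
    carriers = rng.choice(n_hap, size=n_carriers, replace=False)
    donor = int(rng.choice(carriers))

    out = haps.haplotypes.copy()
    donor_row = haps.haplotypes[donor, chrom_idx[flank_local]].copy()
    copy_mask = rng.random((n_carriers, flank_local.size)) < fidelity[None, :]
    block = out[np.ix_(carriers, chrom_idx[flank_local])]
    block[copy_mask] = np.broadcast_to(donor_row, block.shape)[copy_mask]
    out[np.ix_(carriers, chrom_idx[flank_local])] = block

    derived = int(haps.haplotypes[donor, focal])
    out[:, focal] = 1 - derived
    out[carriers, focal] = derived
    return HaplotypeSet(list(haps.individuals), out)


def make_inbred_genotypes(haps: HaplotypeSet, loci: LocusMap,
                          tracts: list[AutozygosityTruth],
                          missing_rate: float = 0.0, seed: int = 0,
                          protect_tracts: bool = True) -> GenotypeMatrix:
    """Collapse haplotype pairs to genotypes, forcing planted autozygosity.

    Individual ``i`` is formed from haplotype rows ``2i`` and ``2i+1``;
    inside each truth tract the second haplotype is overwritten by the
    first, so every SNP in the tract is homozygous.  Genotypes are coded as
    counts of allele 1 (= ``allele_b``).  Missing calls are injected
    uniformly at ``missing_rate``; with ``protect_tracts`` (default) no
    missing call lands inside a truth tract, keeping planted runs intact.
    """
    if not 0.0 <= missing_rate < 1.0:
        raise ConfigurationError("missing_rate must lie in [0, 1)")
    rng = np.random.default_rng(seed)
    ind_index = {name: i for i, name in enumerate(haps.individuals)}
    chrom_idx = loci.chrom_indices()

    by_ind: dict[int, list[AutozygosityTruth]] = {}
    for t in tracts:
        if t.individual not in ind_index:
            raise DomainError(f"unknown individual {t.individual!r}")
        if str(t.chromosome) not in chrom_idx:
            raise DomainError(f"unknown chromosome {t.chromosome!r}")
        pos = loci.pos[chrom_idx[str(t.chromosome)]]
        if t.tract_start < 1 or t.tract_end > pos[-1]:
            raise DomainError(
                f"tract [{t.tract_start}, {t.tract_end}] outside mapped span "
                f"of chromosome {t.chromosome}")
        by_ind.setdefault(ind_index[t.individual], []).append(t)
    for i, ts in by_ind.items():
        ts.sort(key=lambda t: (str(t.chromosome), t.tract_start))
        for a, b in zip(ts, ts[1:]):
            if str(a.chromosome) == str(b.chromosome) and b.tract_start <= a.tract_end:
                raise DomainError(
                    f"overlapping tracts for individual {haps.individuals[i]!r}")

    h = haps.haplotypes.copy()
    protected = np.zeros((haps.n_individuals, haps.n_snps), dtype=bool)
    for i, ts in by_ind.items():
        for t in ts:
            idx = chrom_idx[str(t.chromosome)]
            inside = idx[(loci.pos[idx] >= t.tract_start) & (loci.pos[idx] <= t.tract_end)]
            h[2 * i + 1, inside] = h[2 * i, inside]
            protected[i, inside] = True

    geno = (h[0::2].astype(np.int8) + h[1::2].astype(np.int8))
    if missing_rate > 0:
        miss = rng.random(geno.shape) < missing_rate
        if protect_tracts:
            miss &= ~protected
        geno[miss] = MISSING
    return GenotypeMatrix(list(haps.individuals), geno)
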