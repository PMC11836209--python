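import numpy as np
import pytest

from sweepscan import (GenotypeMatrix, LocusMap, SimConfig,
                       simulate_neutral_haplotypes)


@pytest.fixture(scope="session")
def small_sim():
    """50 individuals x 2 chromosomes x 400 SNPs, neutral."""
    cfg = SimConfig(n_individuals=50, n_snps_per_chrom=400, n_chroms=2,
                    chrom_length=20_000_000, maf_floor=0.05, seed=42)
    return simulate_neutral_haplotypes(cfg)


@pytest.fixture()
def grid_loci():
    """Factory: one chromosome, SNPs on a regular bp grid."""
    def make(n_snps: int, spacing: int = 25_000, chrom: str = "1") -> LocusMap:
        pos = np.arange(1, n_snps + 1) * spacing
        return LocusMap(
            chrom=np.full(n_snps, chrom, dtype=object),
            name=np.asarray([f"s{chrom}_{p}" for p in pos], dtype=object),
            pos=pos,
            allele_a=np.full(n_snps, "A", dtype=object),
            allele_b=np.full(n_snps, "B", dtype=object))
    return make


@pytest.fixture()
def geno_from_rows():
    """Factory: GenotypeMatrix from a list of per-individual genotype rows."""
    def make(rows, names=None) -> GenotypeMatrix:
        arr = np.asarray(rows, dtype=np.int8)
        names = names or [f"i{k}" for k in range(arr.shape[0])]
        return GenotypeMatrix(list(names), arr)
    return make
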