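"""Core in-memory containers shared by every pipeline stage.

Three substrates flow through the pipeline:

* :class:`LocusMap` — the per-SNP coordinate backbone (chromosome, 1-based
  bp position, allele labels).
* :class:`GenotypeMatrix` — diploid calls coded as counts of ``allele_b``
  (0/1/2) with ``MISSING`` (-1) for no-calls; substrate for QC, diversity
  statistics and runs-of-homozygosity detection.
* :class:`HaplotypeSet` — a phased binary matrix with two rows per
  individual (rows ``2i`` and ``2i+1`` belong to individual ``i``);
  substrate for EHH/iHS.  Phasing is a precondition: no missing values.

Coordinates are 1-based bp throughout; intervals are closed ``[start, end]``
except where a writer converts to BED's 0-based half-open convention.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import DataError

#: Sentinel for a missing diploid genotype call.
MISSING: int = -1

#: Sheep (Ovis aries) autosomes; the default autosome set for QC.
SHEEP_AUTOSOMES: frozenset[str] = frozenset(str(c) for c in range(1, 27))


def chrom_sort_key(label: str):
    """Sort chromosomes numerically when possible, lexically otherwise."""
    s = str(label)
    return (0, int(s), "") if s.isdigit() else (1, 0, s)


@dataclass
class LocusMap:
    """Per-SNP metadata aligned column-for-column with the matrices.

    Parameters
    ----------
    chrom : array of str
        Chromosome label per SNP.
    name : array of str
        Unique SNP identifiers.
    pos : array of int
        1-based bp position, strictly increasing within each chromosome.
    allele_a, allele_b : array of str
        Allele labels; genotypes count copies of ``allele_b``.
    """

    chrom: np.ndarray
    name: np.ndarray
    pos: np.ndarray
    allele_a: np.ndarray
    allele_b: np.ndarray
    autosomes: frozenset = field(default=SHEEP_AUTOSOMES)

    def __post_init__(self) -> None:
        self.chrom = np.asarray(self.chrom, dtype=object)
        self.name = np.asarray(self.name, dtype=object)
        self.pos = np.asarray(self.pos, dtype=np.int64)
        self.allele_a = np.asarray(self.allele_a, dtype=object)
        self.allele_b = np.asarray(self.allele_b, dtype=object)
        self.validate()

    # -- basic facts ------------------------------------------------------
    @property
    def n_snps(self) -> int:
        return int(self.pos.shape[0])

    @property
    def is_autosomal(self) -> np.ndarray:
        return np.asarray([str(c) in self.autosomes for c in self.chrom])

    def chromosomes(self) -> list[str]:
        """Unique chromosome labels in natural order of first appearance."""
        seen: dict[str, None] = {}
        for c in self.chrom:
            seen.setdefault(str(c), None)
        return sorted(seen, key=chrom_sort_key)

    def chrom_indices(self) -> dict[str, np.ndarray]:
        """Column index array per chromosome (columns are contiguous)."""
        out: dict[str, np.ndarray] = {}
        for c in self.chromosomes():
            out[c] = np.flatnonzero(np.asarray([str(x) == c for x in self.chrom]))
        return out

    def validate(self) -> None:
        n = len(self.pos)
        for arr, nm in ((self.chrom, "chrom"), (self.name, "name"),
                        (self.allele_a, "allele_a"), (self.allele_b, "allele_b")):
            if len(arr) != n:
                raise DataError(f"LocusMap field {nm!r} has length {len(arr)}, expected {n}")
        if len(set(self.name)) != n:
            raise DataError("SNP names are not unique")
        for c, idx in self.chrom_indices().items():
            p = self.pos[idx]
            if np.any(np.diff(p) <= 0):
                raise DataError(f"positions not strictly increasing on chromosome {c}")

    def subset(self, idx: np.ndarray) -> "LocusMap":
        return LocusMap(self.chrom[idx], self.name[idx], self.pos[idx],
                        self.allele_a[idx], self.allele_b[idx], self.autosomes)

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame({
            "chrom": self.chrom, "name": self.name, "pos": self.pos,
            "allele_a": self.allele_a, "allele_b": self.allele_b,
        })


@dataclass
class GenotypeMatrix:
    """Diploid calls: individuals x SNPs, values in {0, 1, 2, MISSING}."""

    individuals: list[str]
    values: np.ndarray  # int8, n_individuals x n_snps

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.int8)
        if self.values.ndim != 2:
            raise DataError("genotype values must be a 2-D matrix")
        if self.values.shape[0] != len(self.individuals):
            raise DataError("row count does not match number of individuals")
        bad = ~np.isin(self.values, (0, 1, 2, MISSING))
        if bad.any():
            raise DataError("genotype codes outside {0, 1, 2, missing}")

    @property
    def n_individuals(self) -> int:
        return self.values.shape[0]

    @property
    def n_snps(self) -> int:
        return self.values.shape[1]

    def subset(self, rows: np.ndarray | None = None,
               cols: np.ndarray | None = None) -> "GenotypeMatrix":
        vals = self.values
        inds = self.individuals
        if rows is not None:
            vals = vals[rows]
            inds = [inds[i] for i in np.atleast_1d(np.arange(len(inds))[rows])]
        if cols is not None:
            vals = vals[:, cols]
        return GenotypeMatrix(list(inds), vals.copy())


@dataclass
class HaplotypeSet:
    """Phased binary haplotypes: 2*n_individuals x n_SNPs, rows paired."""

    individuals: list[str]
    haplotypes: np.ndarray  # uint8, 2n x m
    phased: bool = True

    def __post_init__(self) -> None:
        self.haplotypes = np.asarray(self.haplotypes, dtype=np.uint8)
        if not self.phased:
            raise DataError("HaplotypeSet requires phased haplotypes")
        if self.haplotypes.ndim != 2 or self.haplotypes.shape[0] != 2 * len(self.individuals):
            raise DataError("haplotype matrix must have two rows per individual")
        if self.haplotypes.size and self.haplotypes.max() > 1:
            raise DataError("haplotype entries must be 0/1 (no missing values)")

    @property
    def n_individuals(self) -> int:
        return len(self.individuals)

    @property
    def n_haplotypes(self) -> int:
        return self.haplotypes.shape[0]

    @property
    def n_snps(self) -> int:
        return self.haplotypes.shape[1]

    def allele_frequency(self) -> np.ndarray:
        """Frequency of allele 1 per SNP across all haplotypes."""
        return self.haplotypes.mean(axis=0)
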