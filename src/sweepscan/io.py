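"""Genotype/haplotype file I/O and the quality-control filter.

Formats:

* PLINK text PED/MAP (read + write) for diploid genotypes.  Genotypes are
  recoded on read to counts of ``allele_b``, defined per SNP as the
  lexically later of the two observed allele labels; ``0 0`` (and any
  half-missing pair) is a missing call.
* Phased VCF (read via cyvcf2, write as plain text) for haplotypes;
  unphased records are rejected — phase/impute externally first.
* Truth/report tables as TSV.

QC mirrors standard SNP-array practice: autosomes only, per-sample and
per-SNP call rate >= 90 %, MAF >= 0.05, applied in that order.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .containers import MISSING, GenotypeMatrix, HaplotypeSet, LocusMap, chrom_sort_key
from .errors import DataError, ParseError

__all__ = [
    "QCReport",
    "read_ped_map",
    "write_ped_map",
    "read_phased_vcf",
    "write_phased_vcf",
    "qc_filter",
]


# ---------------------------------------------------------------------------
# PLINK text PED/MAP
# ---------------------------------------------------------------------------

def read_ped_map(ped_path, map_path) -> tuple[GenotypeMatrix, LocusMap]:
    """Read a PLINK text fileset into (GenotypeMatrix, LocusMap).

    Loci are sorted by (chromosome, position); ``allele_b`` at each SNP is
    the lexically later of the observed alleles and genotype values count
    its copies.
    """
    map_df = pd.read_csv(map_path, sep=r"\s+", header=None,
                         names=["chrom", "name", "cm", "pos"], dtype=str)
    if map_df.shape[1] != 4:
        raise ParseError(f"{map_path}: MAP file must have 4 columns")
    m = len(map_df)

    individuals: list[str] = []
    allele_rows: list[np.ndarray] = []
    with open(ped_path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip():
                continue
            fields = line.split()
            if len(fields) != 6 + 2 * m:
                raise ParseError(
                    f"{ped_path}:{lineno}: expected {6 + 2 * m} fields "
                    f"(6 + 2x{m} SNPs), found {len(fields)}")
            individuals.append(fields[1])
            allele_rows.append(np.asarray(fields[6:], dtype=object))
    if not individuals:
        raise ParseError(f"{ped_path}: no samples")

    alleles = np.stack(allele_rows)          # n x 2m
    a1 = alleles[:, 0::2]
    a2 = alleles[:, 1::2]
    missing = (a1 == "0") | (a2 == "0")

    geno = np.zeros((len(individuals), m), dtype=np.int8)
    allele_a = np.empty(m, dtype=object)
    allele_b = np.empty(m, dtype=object)
    for j in range(m):
        obs = set(a1[:, j][~missing[:, j]]) | set(a2[:, j][~missing[:, j]])
        if len(obs) > 2:
            raise DataError(
                f"SNP {map_df['name'][j]!r} has >2 alleles: {sorted(obs)}")
        if not obs:
            allele_a[j], allele_b[j] = "0", "0"
            geno[:, j] = MISSING
            continue
        ordered = sorted(obs)
        allele_a[j] = ordered[0] if len(ordered) == 2 else "0"
        allele_b[j] = ordered[-1]
        geno[:, j] = ((a1[:, j] == allele_b[j]).astype(np.int8)
                      + (a2[:, j] == allele_b[j]).astype(np.int8))
        geno[missing[:, j], j] = MISSING

    chrom_arr = map_df["chrom"].to_numpy(dtype=object)
    pos_arr = map_df["pos"].astype(np.int64).to_numpy()
    order = np.asarray(sorted(range(m), key=lambda j: (chrom_sort_key(chrom_arr[j]),
                                                       int(pos_arr[j]))))
    loci = LocusMap(chrom=chrom_arr[order],
                    name=map_df["name"].to_numpy(dtype=object)[order],
                    pos=pos_arr[order],
                    allele_a=allele_a[order], allele_b=allele_b[order])
    return GenotypeMatrix(individuals, geno[:, order]), loci


def write_ped_map(g: GenotypeMatrix, loci: LocusMap, ped_path, map_path,
                  family_id: str = "F0") -> None:
    """Write a PLINK text fileset (white-space separated)."""
    with open(map_path, "w") as fh:
        for c, nm, p in zip(loci.chrom, loci.name, loci.pos):
            fh.write(f"{c}\t{nm}\t0\t{p}\n")
    a = loci.allele_a.copy()
    b = loci.allele_b.copy()
    a[a == "0"] = b[a == "0"]  # monomorphic: write the single observed allele
    pairs = {0: np.char.add(np.char.add(a.astype(str), " "), a.astype(str)),
             1: np.char.add(np.char.add(a.astype(str), " "), b.astype(str)),
             2: np.char.add(np.char.add(b.astype(str), " "), b.astype(str))}
    with open(ped_path, "w") as fh:
        for i, ind in enumerate(g.individuals):
            row = g.values[i]
            cells = np.where(row == 0, pairs[0],
                             np.where(row == 1, pairs[1],
                                      np.where(row == 2, pairs[2], "0 0")))
            fh.write(f"{family_id} {ind} 0 0 0 -9 " + " ".join(cells) + "\n")


# ---------------------------------------------------------------------------
# Phased VCF
# ---------------------------------------------------------------------------

def read_phased_vcf(vcf_path) -> tuple[HaplotypeSet, LocusMap]:
    """Read a fully phased, biallelic VCF into (HaplotypeSet, LocusMap)."""
    from cyvcf2 import VCF

    v = VCF(str(vcf_path))
    individuals = list(v.samples)
    chroms, names, positions, ref, alt = [], [], [], [], []
    columns: list[np.ndarray] = []
    for var in v:
        if len(var.ALT) != 1:
            raise DataError(f"multiallelic record {var.ID or var.POS} not supported")
        gts = np.asarray(var.genotypes)            # n x 3: a0, a1, phased
        if not gts[:, 2].all():
            raise DataError(
                f"unphased genotype at {var.CHROM}:{var.POS}; phase/impute "
                "externally (e.g. Beagle) before the iHS scan")
        if (gts[:, :2] < 0).any():
            raise DataError(f"missing genotype at {var.CHROM}:{var.POS}; "
                            "phased input must be complete")
        columns.append(gts[:, :2].reshape(-1).astype(np.uint8))
        chroms.append(var.CHROM)
        names.append(var.ID or f"{var.CHROM}:{var.POS}")
        positions.append(var.POS)
        ref.append(var.REF)
        alt.append(var.ALT[0])
    if not columns:
        raise DataError(f"{vcf_path}: no variant records")
    loci = LocusMap(np.asarray(chroms, dtype=object), np.asarray(names, dtype=object),
                    np.asarray(positions), np.asarray(ref, dtype=object),
                    np.asarray(alt, dtype=object))
    return HaplotypeSet(individuals, np.stack(columns, axis=1)), loci


def write_phased_vcf(haps: HaplotypeSet, loci: LocusMap, vcf_path) -> None:
    """Write haplotypes as an uncompressed phased VCF (GT only)."""
    h = haps.haplotypes
    with open(vcf_path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write("##source=sweepscan\n")
        for c in loci.chromosomes():
            idx = loci.chrom_indices()[c]
            fh.write(f"##contig=<ID={c},length={int(loci.pos[idx][-1]) + 1}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                 + "\t".join(haps.individuals) + "\n")
        for j in range(loci.n_snps):
            gts = "\t".join(f"{h[2 * i, j]}|{h[2 * i + 1, j]}"
                            for i in range(haps.n_individuals))
            fh.write(f"{loci.chrom[j]}\t{loci.pos[j]}\t{loci.name[j]}\t"
                     f"{loci.allele_a[j]}\t{loci.allele_b[j]}\t.\t.\t.\tGT\t{gts}\n")


# ---------------------------------------------------------------------------
# Quality control
# ---------------------------------------------------------------------------

@dataclass
class QCReport:
    """Counts removed by each QC step, in application order."""

    n_snps_in: int
    n_samples_in: int
    removed_nonautosomal: int
    removed_sample_callrate: int
    removed_snp_callrate: int
    removed_maf: int
    n_snps_out: int
    n_samples_out: int
    maf_min: float
    snp_call_min: float
    sample_call_min: float

    def __str__(self) -> str:
        return (
            f"QC: {self.n_snps_in} SNPs / {self.n_samples_in} samples in; "
            f"removed {self.removed_nonautosomal} non-autosomal SNPs, "
            f"{self.removed_sample_callrate} samples (call rate < {self.sample_call_min:g}), "
            f"{self.removed_snp_callrate} SNPs (call rate < {self.snp_call_min:g}), "
            f"{self.removed_maf} SNPs (MAF < {self.maf_min:g}); "
            f"{self.n_snps_out} SNPs / {self.n_samples_out} samples retained.")

    def to_series(self) -> pd.Series:
        return pd.Series(vars(self))


def _call_rates(values: np.ndarray, axis: int) -> np.ndarray:
    return (values != MISSING).mean(axis=axis)


def compute_maf(values: np.ndarray) -> np.ndarray:
    """Per-SNP minor allele frequency from non-missing diploid calls.

    SNPs with zero non-missing calls get NaN.
    """
    called = values != MISSING
    n = called.sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        p = np.where(called, values, 0).sum(axis=0) / (2.0 * n)
    p = np.where(n > 0, p, np.nan)
    return np.minimum(p, 1.0 - p)


def qc_filter(g: GenotypeMatrix, loci: LocusMap, maf_min: float = 0.05,
              snp_call_min: float = 0.90, sample_call_min: float = 0.90,
              ) -> tuple[GenotypeMatrix, LocusMap, QCReport]:
    """Apply the QC filters in fixed order and report per-step removals.

    Order: (1) drop non-autosomal loci; (2) drop samples with call rate
    below ``sample_call_min`` (computed on autosomal loci); (3) drop SNPs
    with call rate below ``snp_call_min``; (4) drop SNPs with MAF below
    ``maf_min``, recomputed on the retained samples.
    """
    if g.n_snps != loci.n_snps:
        raise DataError("genotype matrix and locus map have different SNP counts")
    n_snps_in, n_samples_in = g.n_snps, g.n_individuals

    auto = loci.is_autosomal
    removed_nonauto = int((~auto).sum())
    vals = g.values[:, auto]
    loci1 = loci.subset(np.flatnonzero(auto))

    keep_sample = _call_rates(vals, axis=1) >= sample_call_min
    removed_samples = int((~keep_sample).sum())
    vals = vals[keep_sample]
    individuals = [ind for ind, k in zip(g.individuals, keep_sample) if k]
    if not individuals:
        raise DataError("QC removed every sample")

    keep_call = _call_rates(vals, axis=0) >= snp_call_min
    removed_callrate = int((~keep_call).sum())
    vals = vals[:, keep_call]
    loci2 = loci1.subset(np.flatnonzero(keep_call))

    maf = compute_maf(vals)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        keep_maf = maf >= maf_min
    keep_maf &= ~np.isnan(maf)
    removed_maf = int((~keep_maf).sum())
    vals = vals[:, keep_maf]
    loci3 = loci2.subset(np.flatnonzero(keep_maf))
    if loci3.n_snps == 0:
        raise DataError("QC removed every SNP")

    report = QCReport(
        n_snps_in=n_snps_in, n_samples_in=n_samples_in,
        removed_nonautosomal=removed_nonauto,
        removed_sample_callrate=removed_samples,
        removed_snp_callrate=removed_callrate,
        removed_maf=removed_maf,
        n_snps_out=loci3.n_snps, n_samples_out=len(individuals),
        maf_min=maf_min, snp_call_min=snp_call_min,
        sample_call_min=sample_call_min)
    return GenotypeMatrix(individuals, vals.copy()), loci3, report
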