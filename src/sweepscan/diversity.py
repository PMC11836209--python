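"""Genetic-diversity and homozygosity-based inbreeding statistics.

Implements the single-population summaries a 50K-array diversity table
reports: the MAF spectrum over seven printed frequency classes, the
proportion of polymorphic SNPs P_N (MAF > 0.05), observed and expected
heterozygosity (He with the small-sample correction n/(n-1)), pairwise
identity-by-state distance D = 1 - D_ST with
D_ST = (IBS2 + 0.5*IBS1) / N, and the excess-homozygosity inbreeding
coefficient F_HOM = (O - E) / (L - E).
"""

from __future__ import annotations

import itertools
import warnings

import numpy as np
import pandas as pd

from .containers import MISSING, GenotypeMatrix
from .errors import DataError
from .io import compute_maf

__all__ = [
    "MAF_CLASS_LABELS",
    "maf_spectrum",
    "proportion_polymorphic",
    "ho_he",
    "pairwise_distance",
    "f_hom",
    "diversity_summary",
]

#: Seven printed MAF classes; the first is closed [0, 0.01], the rest (lo, hi].
MAF_CLASS_EDGES = (0.01, 0.05, 0.1, 0.2, 0.3, 0.4)
MAF_CLASS_LABELS = ("0-0.01", "0.01-0.05", "0.05-0.1", "0.1-0.2",
                    "0.2-0.3", "0.3-0.4", "0.4-0.5")


def maf_spectrum(g: GenotypeMatrix) -> tuple[np.ndarray, pd.Series]:
    """Per-SNP MAF plus the 7-class histogram.

    SNPs with zero non-missing calls get NaN and are excluded from the
    histogram; the histogram therefore totals the number of SNPs with a
    defined MAF.
    """
    maf = compute_maf(g.values)
    ok = ~np.isnan(maf)
    bins = np.digitize(maf[ok], MAF_CLASS_EDGES, right=True)
    counts = np.bincount(bins, minlength=7)
    return maf, pd.Series(counts, index=list(MAF_CLASS_LABELS), name="n_snps")


def proportion_polymorphic(mafs: np.ndarray) -> float:
    """P_N: fraction of SNPs with MAF strictly greater than 0.05."""
    mafs = np.asarray(mafs, dtype=float)
    mafs = mafs[~np.isnan(mafs)]
    if mafs.size == 0:
        raise DataError("no SNPs with a defined MAF")
    return float((mafs > 0.05).mean())


def ho_he(g: GenotypeMatrix) -> pd.DataFrame:
    """Per-SNP observed and expected heterozygosity.

    Ho = het calls / non-missing calls; He = 2 p (1-p) * n/(n-1) with n the
    non-missing diploid count (small-sample corrected, PLINK-style).  SNPs
    with n <= 1 are excluded with a warning.
    """
    vals = g.values
    called = vals != MISSING
    n = called.sum(axis=0)
    if (n <= 1).any():
        warnings.warn(f"{int((n <= 1).sum())} SNP(s) with <2 non-missing "
                      "calls excluded from Ho/He")
    keep = n > 1
    nk = n[keep]
    het = ((vals == 1) & called).sum(axis=0)[keep]
    p = np.where(called, vals, 0).sum(axis=0)[keep] / (2.0 * nk)
    ho = het / nk
    he = 2.0 * p * (1.0 - p) * nk / (nk - 1.0)
    return pd.DataFrame({"snp_index": np.arange(vals.shape[1])[keep],
                         "n": nk, "ho": ho, "he": he})


def pairwise_distance(g: GenotypeMatrix) -> pd.DataFrame:
    """All-pairs IBS sharing and genetic distance D = 1 - D_ST.

    For each pair the locus set is those non-missing in both individuals
    (pairwise deletion); IBS2/IBS1/IBS0 count loci sharing 2/1/0 alleles
    identical by state.  Pairs with no shared complete locus are skipped
    with a warning.
    """
    if g.n_individuals < 2:
        raise DataError("pairwise distance needs >=2 individuals")
    vals = g.values
    called = vals != MISSING
    rows = []
    for i, j in itertools.combinations(range(g.n_individuals), 2):
        both = called[i] & called[j]
        n = int(both.sum())
        if n == 0:
            warnings.warn(f"pair ({g.individuals[i]}, {g.individuals[j]}) "
                          "shares no complete locus; skipped")
            continue
        diff = np.abs(vals[i, both].astype(np.int16) - vals[j, both])
        ibs2 = int((diff == 0).sum())
        ibs1 = int((diff == 1).sum())
        ibs0 = n - ibs2 - ibs1
        dst = (ibs2 + 0.5 * ibs1) / n
        rows.append((g.individuals[i], g.individuals[j], ibs0, ibs1, ibs2,
                     n, dst, 1.0 - dst))
    return pd.DataFrame(rows, columns=["ind_i", "ind_j", "ibs0", "ibs1",
                                       "ibs2", "n", "d_st", "d"])


def f_hom(g: GenotypeMatrix) -> pd.Series:
    """Excess-homozygosity inbreeding coefficient per individual.

    F_HOM = (O - E) / (L - E) where O is the observed homozygous count over
    the individual's non-missing loci, L that non-missing count, and E the
    sum over those loci of 1 - 2 p (1-p) * n/(n-1) using cohort allele
    frequencies (so E matches the He convention).  Degenerate individuals
    (L == E) get NaN.
    """
    vals = g.values
    called = vals != MISSING
    n = called.sum(axis=0)
    usable = n > 1
    with np.errstate(invalid="ignore", divide="ignore"):
        p = np.where(called, vals, 0).sum(axis=0) / (2.0 * n)
        exp_hom_per_locus = 1.0 - 2.0 * p * (1.0 - p) * n / (n - 1.0)
    out = np.full(g.n_individuals, np.nan)
    for i in range(g.n_individuals):
        mask = called[i] & usable
        L = int(mask.sum())
        if L == 0:
            continue
        O = int(((vals[i] == 0) | (vals[i] == 2))[mask].sum())
        E = float(exp_hom_per_locus[mask].sum())
        if abs(L - E) < 1e-12:
            continue
        out[i] = (O - E) / (L - E)
    return pd.Series(out, index=list(g.individuals), name="f_hom")


def diversity_summary(g: GenotypeMatrix) -> pd.Series:
    """One-row summary mirroring a diversity table: MAF, P_N, Ho, He, D, F_HOM."""
    maf, _ = maf_spectrum(g)
    hh = ho_he(g)
    pw = pairwise_distance(g)
    fh = f_hom(g)
    ok = ~np.isnan(maf)
    return pd.Series({
        "maf_mean": float(np.mean(maf[ok])),
        "maf_sd": float(np.std(maf[ok], ddof=1)) if ok.sum() > 1 else np.nan,
        "p_n": proportion_polymorphic(maf),
        "ho_mean": float(hh["ho"].mean()), "ho_sd": float(hh["ho"].std(ddof=1)),
        "he_mean": float(hh["he"].mean()), "he_sd": float(hh["he"].std(ddof=1)),
        "d_mean": float(pw["d"].mean()), "d_sd": float(pw["d"].std(ddof=1)),
        "f_hom_mean": float(fh.mean()), "f_hom_sd": float(fh.std(ddof=1)),
    })
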