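"""Runs of homozygosity: sliding-window detection, classing, F_ROH, islands.

The detector follows the sliding-window semantics of the detectRUNS family
of tools: a fixed-size window of ``min_snps`` SNPs slides one SNP at a time
over each individual x chromosome; a window "hits" when it holds at most
``max_het`` heterozygous and ``max_missing`` missing calls; a SNP becomes a
run candidate when the fraction of hit windows among the windows covering
it exceeds ``window_hit_proportion``.  Maximal candidate stretches are
split wherever adjacent SNPs are more than ``max_gap`` apart and retained
as runs only if they meet the SNP-count, physical-length and SNP-density
floors.

The window size itself comes from :func:`min_snp_threshold`, the
false-positive bound of Purfield and colleagues:

    L = ceil( ln(a / (n_s * n_i)) / ln(1 - het) )

so that fewer than ``a`` chance runs of L homozygous SNPs are expected in
the whole dataset given mean heterozygosity ``het``.

F_ROH for an individual is the summed run length divided by the SNP-covered
autosomal genome length; ROH *islands* are stretches of consecutive SNPs
whose ROH incidence across individuals reaches a population threshold
(default 10 %), read as selective-sweep signatures.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .containers import MISSING, GenotypeMatrix, LocusMap
from .errors import DataError, DomainError

__all__ = [
    "ROHParams",
    "min_snp_threshold",
    "detect_roh",
    "validate_segments",
    "classify_roh",
    "f_roh",
    "correlate_inbreeding",
    "snp_roh_incidence",
    "roh_islands",
    "ROH_CLASS_LABELS",
]

#: Length classes in Mb: [1,5), [5,10), [10,20), [20,40), [40, inf).
ROH_CLASS_EDGES_MB = (1.0, 5.0, 10.0, 20.0, 40.0)
ROH_CLASS_LABELS = ("1-5", "5-10", "10-20", "20-40", ">40")

SEGMENT_COLUMNS = ["individual", "chrom", "start", "end", "n_snps", "length"]


def min_snp_threshold(a: float, n_s: int, n_i: int, het: float,
                      raw: bool = False) -> int | float:
    """Minimum SNPs per window/run bounding the false-positive ROH rate.

    Parameters
    ----------
    a : allowed expected number of chance runs (false-positive rate).
    n_s : genotyped SNPs per individual.
    n_i : genotyped individuals.
    het : mean heterozygosity per SNP.
    raw : return the un-ceiled value (diagnostics).
    """
    if not 0 < a < 1:
        raise DomainError("a must lie in (0, 1)")
    if n_s < 1 or n_i < 1:
        raise DomainError("n_s and n_i must be >= 1")
    if not 0 < het < 1:
        raise DomainError("het must lie strictly in (0, 1)")
    value = math.log(a / (n_s * n_i)) / math.log(1.0 - het)
    return value if raw else int(math.ceil(value))


@dataclass(frozen=True)
class ROHParams:
    """Sliding-window ROH parameters (defaults = 50K-array conventions)."""

    min_snps: int = 41
    max_het: int = 1
    max_missing: int = 2
    max_gap: int = 1_000_000
    min_length: int = 1_000_000
    #: density floor expressed as a bp-per-SNP ceiling (1 SNP per 100 kb)
    max_bp_per_snp: int = 100_000
    window_hit_proportion: float = 0.05

    def __post_init__(self) -> None:
        for f in ("min_snps", "max_gap", "min_length", "max_bp_per_snp"):
            if getattr(self, f) <= 0:
                raise DomainError(f"{f} must be positive")
        if self.max_het < 0 or self.max_missing < 0:
            raise DomainError("max_het and max_missing must be >= 0")
        if not 0 <= self.window_hit_proportion < 1:
            raise DomainError("window_hit_proportion must lie in [0, 1)")

    @classmethod
    def from_data(cls, g: GenotypeMatrix, a: float = 0.05, **kwargs) -> "ROHParams":
        """Window size from the false-positive bound on this dataset."""
        called = g.values != MISSING
        het = float(((g.values == 1) & called).sum() / called.sum())
        w = min_snp_threshold(a, g.n_snps, g.n_individuals, het)
        return cls(min_snps=w, **kwargs)


def _sliding_sum(x: np.ndarray, w: int) -> np.ndarray:
    c = np.concatenate([[0], np.cumsum(x)])
    return c[w:] - c[:-w]


def _candidate_mask(geno_row: np.ndarray, params: ROHParams) -> np.ndarray:
    """Per-SNP run-candidate flags for one individual on one chromosome."""
    m = geno_row.shape[0]
    w = params.min_snps
    het = (geno_row == 1).astype(np.int32)
    miss = (geno_row == MISSING).astype(np.int32)
    hit = ((_sliding_sum(het, w) <= params.max_het)
           & (_sliding_sum(miss, w) <= params.max_missing))
    n_win = m - w + 1
    # SNP j is covered by windows starting in [max(0, j-w+1), min(j, n_win-1)]
    hit_cum = np.concatenate([[0], np.cumsum(hit)])
    j = np.arange(m)
    lo = np.maximum(0, j - w + 1)
    hi = np.minimum(j, n_win - 1)
    n_cover = hi - lo + 1
    n_hits = hit_cum[hi + 1] - hit_cum[lo]
    return n_hits / n_cover > params.window_hit_proportion


def _runs_from_mask(mask: np.ndarray) -> list[tuple[int, int]]:
    """Maximal True stretches of ``mask`` as (first, last) index pairs."""
    idx = np.flatnonzero(mask)
    if idx.size == 0:
        return []
    breaks = np.flatnonzero(np.diff(idx) > 1)
    starts = np.concatenate([[0], breaks + 1])
    ends = np.concatenate([breaks, [idx.size - 1]])
    return [(int(idx[s]), int(idx[e])) for s, e in zip(starts, ends)]


def detect_roh(g: GenotypeMatrix, loci: LocusMap,
               params: ROHParams | None = None) -> pd.DataFrame:
    """Detect runs of homozygosity for every individual.

    Returns a table with columns ``individual, chrom, start, end, n_snps,
    length`` (bp positions of the first/last SNP in the run, length =
    end - start + 1).  Chromosomes holding fewer SNPs than the window are
    skipped with a warning.
    """
    if params is None:
        params = ROHParams.from_data(g)
    rows: list[tuple] = []
    chrom_idx = loci.chrom_indices()
    skipped = [c for c, idx in chrom_idx.items() if idx.size < params.min_snps]
    if skipped:
        warnings.warn(f"chromosome(s) {skipped} have fewer than "
                      f"{params.min_snps} SNPs; skipped")
    for c, idx in chrom_idx.items():
        if idx.size < params.min_snps:
            continue
        pos = loci.pos[idx]
        gaps_ok = np.diff(pos) <= params.max_gap
        for i, ind in enumerate(g.individuals):
            cand = _candidate_mask(g.values[i, idx], params)
            for first, last in _runs_from_mask(cand):
                # split candidate stretch at physical gaps > max_gap
                sub_start = first
                for k in range(first, last):
                    if not gaps_ok[k]:
                        rows.extend(_emit(ind, c, pos, idx, sub_start, k, params))
                        sub_start = k + 1
                rows.extend(_emit(ind, c, pos, idx, sub_start, last, params))
    return pd.DataFrame(rows, columns=SEGMENT_COLUMNS)


def _emit(ind: str, chrom: str, pos: np.ndarray, idx: np.ndarray,
          first: int, last: int, params: ROHParams) -> list[tuple]:
    n_snps = last - first + 1
    length = int(pos[last] - pos[first] + 1)
    if (n_snps >= params.min_snps and length >= params.min_length
            and length / n_snps <= params.max_bp_per_snp):
        return [(ind, chrom, int(pos[first]), int(pos[last]), n_snps, length)]
    return []


def validate_segments(segments: pd.DataFrame, g: GenotypeMatrix,
                      loci: LocusMap, params: ROHParams) -> None:
    """Re-check every emitted segment against the ROH constraints.

    Independent of the scanner: verifies SNP count, length, internal gaps
    and density directly from the locus map.  Raises DataError on violation.
    """
    chrom_idx = loci.chrom_indices()
    for _, seg in segments.iterrows():
        idx = chrom_idx[str(seg["chrom"])]
        pos = loci.pos[idx]
        inside = (pos >= seg["start"]) & (pos <= seg["end"])
        n_snps = int(inside.sum())
        length = int(seg["end"] - seg["start"] + 1)
        if n_snps != seg["n_snps"]:
            raise DataError(f"segment SNP count mismatch: {seg.to_dict()}")
        if n_snps < params.min_snps or length < params.min_length:
            raise DataError(f"segment below size floors: {seg.to_dict()}")
        if length / n_snps > params.max_bp_per_snp:
            raise DataError(f"segment below density floor: {seg.to_dict()}")
        if np.diff(pos[inside]).max(initial=0) > params.max_gap:
            raise DataError(f"segment contains gap > max_gap: {seg.to_dict()}")


def classify_roh(segments: pd.DataFrame, loci: LocusMap | None = None,
                 individuals: list[str] | None = None) -> pd.DataFrame:
    """Summarize runs by the five printed length classes.

    Returns per class: count, percent of all runs, mean length (Mb) and —
    when ``loci`` and ``individuals`` are given — the mean and SD over
    individuals of the per-class F_ROH contribution.
    """
    out = pd.DataFrame(index=list(ROH_CLASS_LABELS))
    if len(segments) == 0:
        out["count"] = 0
        out["percent"] = 0.0
        out["mean_length_mb"] = np.nan
        out["froh_mean"] = np.nan
        out["froh_sd"] = np.nan
        return out
    length_mb = segments["length"].to_numpy() / 1e6
    cls = np.digitize(length_mb, ROH_CLASS_EDGES_MB) - 1  # [1,5) -> 0 ... [40,inf) -> 4
    cls = np.clip(cls, 0, 4)
    counts = np.bincount(cls, minlength=5)
    out["count"] = counts
    out["percent"] = 100.0 * counts / counts.sum()
    out["mean_length_mb"] = [length_mb[cls == k].mean() if counts[k] else np.nan
                             for k in range(5)]
    if loci is not None and individuals is not None:
        l_genome = genome_length(loci)
        froh_mean, froh_sd = [], []
        for k in range(5):
            sub = segments.loc[cls == k]
            per_ind = sub.groupby("individual")["length"].sum()
            contrib = pd.Series(0.0, index=list(individuals))
            contrib.loc[per_ind.index] = per_ind / l_genome
            froh_mean.append(float(contrib.mean()))
            froh_sd.append(float(contrib.std(ddof=1)))
        out["froh_mean"] = froh_mean
        out["froh_sd"] = froh_sd
    else:
        out["froh_mean"] = np.nan
        out["froh_sd"] = np.nan
    return out


def genome_length(loci: LocusMap) -> int:
    """SNP-covered autosomal genome length: sum of last-first+1 per autosome."""
    total = 0
    auto = loci.is_autosomal
    for c, idx in loci.chrom_indices().items():
        idx = idx[auto[idx]]
        if idx.size:
            total += int(loci.pos[idx][-1] - loci.pos[idx][0] + 1)
    if total == 0:
        raise DataError("no autosomal SNP coverage; genome length is zero")
    return total


def f_roh(segments: pd.DataFrame, loci: LocusMap,
          individuals: list[str]) -> pd.Series:
    """Per-individual F_ROH = summed run length / SNP-covered genome length."""
    l_genome = genome_length(loci)
    out = pd.Series(0.0, index=list(individuals), name="f_roh")
    if len(segments):
        per_ind = segments.groupby("individual")["length"].sum()
        out.loc[per_ind.index] = per_ind / l_genome
    return out


def correlate_inbreeding(f_roh_vec, f_hom_vec) -> float:
    """Pearson correlation between the two inbreeding coefficients."""
    x = np.asarray(f_roh_vec, dtype=float)
    y = np.asarray(f_hom_vec, dtype=float)
    if x.shape != y.shape or x.size < 3:
        raise DataError("need equal-length vectors with >=3 individuals")
    ok = ~(np.isnan(x) | np.isnan(y))
    x, y = x[ok], y[ok]
    if x.size < 3 or np.all(x == x[0]) or np.all(y == y[0]):
        warnings.warn("correlation undefined (zero variance)")
        return float("nan")
    return float(stats.pearsonr(x, y).statistic)


def snp_roh_incidence(segments: pd.DataFrame, loci: LocusMap,
                      n_individuals: int) -> np.ndarray:
    """Per-SNP proportion of individuals whose ROH covers the SNP."""
    cover = np.zeros(loci.n_snps, dtype=np.int64)
    chrom_idx = loci.chrom_indices()
    for _, seg in segments.iterrows():
        idx = chrom_idx[str(seg["chrom"])]
        pos = loci.pos[idx]
        inside = idx[(pos >= seg["start"]) & (pos <= seg["end"])]
        cover[inside] += 1
    return cover / n_individuals


def roh_islands(incidence: np.ndarray, loci: LocusMap,
                threshold: float = 0.10) -> pd.DataFrame:
    """Maximal stretches of consecutive SNPs with incidence >= threshold.

    Returns one row per island: chrom, start/end bp, start/end SNP names,
    SNP count, and the peak incidence with its SNP.
    """
    incidence = np.asarray(incidence, dtype=float)
    if incidence.shape[0] != loci.n_snps:
        raise DataError("incidence vector not aligned to locus map")
    rows = []
    for c, idx in loci.chrom_indices().items():
        mask = incidence[idx] >= threshold
        for first, last in _runs_from_mask(mask):
            sel = idx[first:last + 1]
            peak_local = sel[int(np.argmax(incidence[sel]))]
            rows.append((c, int(loci.pos[sel[0]]), int(loci.pos[sel[-1]]),
                         loci.name[sel[0]], loci.name[sel[-1]], sel.size,
                         loci.name[peak_local], float(incidence[peak_local])))
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "start_snp",
                                       "end_snp", "n_snps", "peak_snp",
                                       "peak_incidence"])
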