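"""Independent brute-force oracles used to cross-check the implementation.

These deliberately avoid the package's vectorized code paths: EHH by direct
pairwise haplotype comparison, ROH by explicit per-window loops, interval
overlap by all-pairs enumeration.
"""

from __future__ import annotations

import itertools

import numpy as np

from sweepscan.containers import MISSING


def ehh_pairwise(block: np.ndarray, carriers: np.ndarray,
                 focal: int, flank: int) -> float:
    """EHH at ``flank``: identical carrier pairs over [focal..flank] / all pairs."""
    lo, hi = min(focal, flank), max(focal, flank)
    n = len(carriers)
    total = n * (n - 1) // 2
    same = 0
    for i, j in itertools.combinations(carriers, 2):
        if np.array_equal(block[i, lo:hi + 1], block[j, lo:hi + 1]):
            same += 1
    return same / total


def roh_candidates(geno_row: np.ndarray, min_snps: int, max_het: int,
                   max_missing: int, hit_proportion: float) -> np.ndarray:
    """Per-SNP run-candidate flags by explicit window enumeration."""
    m = geno_row.shape[0]
    w = min_snps
    n_win = m - w + 1
    hits = []
    for s in range(n_win):
        window = geno_row[s:s + w]
        het = int((window == 1).sum())
        miss = int((window == MISSING).sum())
        hits.append(het <= max_het and miss <= max_missing)
    cand = np.zeros(m, dtype=bool)
    for j in range(m):
        covering = [hits[s] for s in range(max(0, j - w + 1),
                                           min(j, n_win - 1) + 1)]
        cand[j] = sum(covering) / len(covering) > hit_proportion
    return cand


def roh_segments(geno_row: np.ndarray, pos: np.ndarray, chrom: str,
                 individual: str, params) -> list[tuple]:
    """Full ROH scan for one individual on one chromosome, loop-by-loop."""
    if geno_row.shape[0] < params.min_snps:
        return []
    cand = roh_candidates(geno_row, params.min_snps, params.max_het,
                          params.max_missing, params.window_hit_proportion)
    segments = []
    run: list[int] = []
    for j in range(geno_row.shape[0] + 1):
        in_run = j < geno_row.shape[0] and cand[j]
        gap_break = (in_run and run
                     and pos[j] - pos[run[-1]] > params.max_gap)
        if in_run and not gap_break:
            run.append(j)
            continue
        if run:
            n_snps = len(run)
            length = int(pos[run[-1]] - pos[run[0]] + 1)
            if (n_snps >= params.min_snps and length >= params.min_length
                    and length / n_snps <= params.max_bp_per_snp):
                segments.append((individual, chrom, int(pos[run[0]]),
                                 int(pos[run[-1]]), n_snps, length))
        run = [j] if in_run else []
    return segments


def overlap_count(regions, intervals) -> int:
    """All-pairs count of >=1 bp overlaps between two 1-based closed sets."""
    count = 0
    for _, r in regions.iterrows():
        for _, b in intervals.iterrows():
            if (str(r["chrom"]) == str(b["chrom"])
                    and b["start"] <= r["end"] and b["end"] >= r["start"]):
                count += 1
    return count
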