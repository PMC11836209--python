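"""Region-level selection-signature calling and interval annotation.

Per-SNP statistics become regions two ways:

* **iHS clusters** — the genome is tiled into non-overlapping windows
  (default 500 kb, 1-based closed ``[k*size+1, (k+1)*size]`` anchored at
  position 1 of each chromosome); a window is called under selection when
  it holds at least ``min_snps`` analyzed SNPs of which at least
  ``min_extreme`` are extreme; adjacent called windows merge into one
  region whose peak is its maximum-|iHS| SNP.
* **ROH islands** arrive from :func:`sweepscan.roh.roh_islands` and are
  intersected with iHS regions via :func:`overlap_regions`.

Called regions can be annotated against a user-supplied BED file of named
intervals (genes, QTL); BED's 0-based half-open coordinates are converted
to the package's 1-based closed convention on read.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .containers import LocusMap
from .errors import ParseError

__all__ = [
    "tile_windows",
    "assign_windows",
    "call_ihs_regions",
    "overlap_regions",
    "read_bed",
    "annotate_intervals",
    "write_regions_bed",
]

DEFAULT_WINDOW_SIZE = 500_000


def tile_windows(loci: LocusMap,
                 window_size: int = DEFAULT_WINDOW_SIZE) -> pd.DataFrame:
    """Non-overlapping windows covering the mapped span of each chromosome."""
    rows = []
    for c, idx in loci.chrom_indices().items():
        last = int(loci.pos[idx][-1])
        n_win = (last - 1) // window_size + 1
        for k in range(n_win):
            rows.append((c, k, k * window_size + 1, (k + 1) * window_size))
    return pd.DataFrame(rows, columns=["chrom", "window", "start", "end"])


def assign_windows(pos: np.ndarray,
                   window_size: int = DEFAULT_WINDOW_SIZE) -> np.ndarray:
    """Window index per 1-based position: pos 500000 -> 0, 500001 -> 1."""
    return (np.asarray(pos, dtype=np.int64) - 1) // window_size


def call_ihs_regions(ihs_results: pd.DataFrame,
                     window_size: int = DEFAULT_WINDOW_SIZE,
                     min_snps: int = 10, min_extreme: int = 5) -> pd.DataFrame:
    """Call windows under selection from extreme-flagged iHS results.

    ``ihs_results`` needs columns chrom, name, pos, abs_ihs, extreme; SNPs
    with NaN |iHS| count as unanalyzed.  Adjacent called windows merge into
    one region (so a region can span multiples of the window size); each
    region reports its analyzed-SNP count, extreme count and peak SNP.
    """
    df = ihs_results.loc[~ihs_results["abs_ihs"].isna(),
                         ["chrom", "name", "pos", "abs_ihs", "extreme"]].copy()
    regions = []
    for c, sub in df.groupby("chrom", sort=False):
        sub = sub.sort_values("pos")
        win = assign_windows(sub["pos"].to_numpy(), window_size)
        agg = pd.DataFrame({"win": win, "extreme": sub["extreme"].to_numpy()})
        stats_ = agg.groupby("win")["extreme"].agg(["size", "sum"])
        called = stats_[(stats_["size"] >= min_snps)
                        & (stats_["sum"] >= min_extreme)].index.to_numpy()
        if called.size == 0:
            continue
        # merge runs of consecutive called window indices
        breaks = np.flatnonzero(np.diff(called) > 1)
        starts = np.concatenate([[0], breaks + 1])
        ends = np.concatenate([breaks, [called.size - 1]])
        for s, e in zip(starts, ends):
            w0, w1 = int(called[s]), int(called[e])
            start, end = w0 * window_size + 1, (w1 + 1) * window_size
            inside = sub[(sub["pos"] >= start) & (sub["pos"] <= end)]
            peak = inside.loc[inside["abs_ihs"].idxmax()]
            regions.append((
                "iHS", str(c), start, end, len(inside),
                int(inside["extreme"].sum()), peak["name"],
                int(peak["pos"]), float(peak["abs_ihs"])))
    return pd.DataFrame(regions, columns=[
        "method", "chrom", "start", "end", "n_snps", "n_extreme",
        "peak_snp", "peak_pos", "peak_value"])


def overlap_regions(regions_a: pd.DataFrame,
                    regions_b: pd.DataFrame) -> pd.DataFrame:
    """Pairwise >=1 bp intersections of two region tables (same chromosome).

    Intersection coordinates are reported with the source intervals kept as
    ``a_start``/``a_end`` and ``b_start``/``b_end``.
    """
    rows = []
    for _, ra in regions_a.iterrows():
        for _, rb in regions_b.iterrows():
            if str(ra["chrom"]) != str(rb["chrom"]):
                continue
            start = max(int(ra["start"]), int(rb["start"]))
            end = min(int(ra["end"]), int(rb["end"]))
            if start <= end:
                rows.append(("overlap", str(ra["chrom"]), start, end,
                             int(ra["start"]), int(ra["end"]),
                             int(rb["start"]), int(rb["end"])))
    return pd.DataFrame(rows, columns=["method", "chrom", "start", "end",
                                       "a_start", "a_end", "b_start", "b_end"])


def read_bed(bed_path) -> pd.DataFrame:
    """Read named intervals from BED; converts to 1-based closed coordinates."""
    rows = []
    with open(bed_path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t") if "\t" in line else line.split()
            if len(fields) < 3:
                raise ParseError(f"{bed_path}:{lineno}: BED line needs >=3 fields")
            try:
                start0, end0 = int(fields[1]), int(fields[2])
            except ValueError as exc:
                raise ParseError(f"{bed_path}:{lineno}: non-integer coordinates") from exc
            if end0 <= start0:
                raise ParseError(f"{bed_path}:{lineno}: end <= start")
            name = fields[3] if len(fields) > 3 else f"interval_{lineno}"
            rows.append((fields[0], start0 + 1, end0, name))
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "name"])


def annotate_intervals(regions: pd.DataFrame, bed_path) -> pd.DataFrame:
    """Attach names of BED intervals overlapping each region by >=1 bp."""
    bed = read_bed(bed_path)
    out = regions.copy()
    annotations, counts = [], []
    for _, r in out.iterrows():
        hits = bed[(bed["chrom"].astype(str) == str(r["chrom"]))
                   & (bed["start"] <= int(r["end"]))
                   & (bed["end"] >= int(r["start"]))]
        annotations.append(",".join(hits["name"]))
        counts.append(len(hits))
    out["annotations"] = annotations
    out["n_annotations"] = counts
    return out


def write_regions_bed(regions: pd.DataFrame, path) -> None:
    """Export regions as BED (0-based half-open on write)."""
    with open(path, "w") as fh:
        for _, r in regions.iterrows():
            name = r.get("peak_snp", r.get("method", "region"))
            fh.write(f"{r['chrom']}\t{int(r['start']) - 1}\t{int(r['end'])}\t{name}\n")
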