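"""EHH, integrated EHH and the standardized integrated haplotype score.

For a focal SNP and one of its alleles, the extended haplotype homozygosity
EHH(x) at a flanking SNP x is the probability that two randomly chosen
carrier haplotypes are identical over the whole interval from the focal SNP
to x:

    EHH(x) = sum_g C(k_g, 2) / C(n_a, 2)

where the k_g are the sizes of the distinct haplotype groups among the n_a
carriers.  Each side of the curve is extended outward until EHH falls below
``ehh_cutoff`` (default 0.05) or the chromosome ends (the side is then
flagged truncated).  iHH is the trapezoid integral of the curve over
physical bp distance, both sides summed; a SNP whose curve is truncated at
a chromosome border while EHH is still above ``border_cutoff`` (default
0.10) is excluded as unreliable.

The unstandardized score is ln(iHH_A / iHH_D) for the ancestral vs derived
allele.  Because true ancestral states are unknown on most arrays, two
assignment strategies are supported: the major (highest-frequency) allele
as ancestral, or repeated random fair-coin assignment.  Scores are
standardized to mean 0 / SD 1 within derived-allele-frequency bins, and
SNPs with |iHS| above ``extreme_threshold`` (default 3.2) are flagged
extreme.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .containers import HaplotypeSet, LocusMap
from .errors import DataError

__all__ = [
    "EHHCurve",
    "assign_ancestral",
    "ehh",
    "ihh",
    "compute_ihh_table",
    "standardize_ihs",
    "ihs_scan",
    "run_random_replicates",
    "call_extreme",
]

DEFAULT_EHH_CUTOFF = 0.05
DEFAULT_BORDER_CUTOFF = 0.10
DEFAULT_EXTREME_THRESHOLD = 3.2


@dataclass
class EHHCurve:
    """One EHH decay curve: positions (bp) ordered left-to-right, focal included."""

    focal_name: str
    focal_pos: int
    allele: int
    positions: np.ndarray
    values: np.ndarray
    truncated_left: bool
    truncated_right: bool

    @property
    def focal_index(self) -> int:
        return int(np.flatnonzero(self.positions == self.focal_pos)[0])


def assign_ancestral(haps: HaplotypeSet, mode: str = "major_allele",
                     seed: int | None = None) -> np.ndarray:
    """Ancestral allele per SNP: -1 marks monomorphic (unanalyzable) SNPs.

    ``major_allele``: the higher-frequency allele; an exact 0.5 tie goes to
    allele 0.  ``random``: a fair coin per SNP drawn from ``seed``.
    """
    freq1 = haps.allele_frequency()
    mono = (freq1 == 0.0) | (freq1 == 1.0)
    if mode == "major_allele":
        anc = (freq1 > 0.5).astype(np.int8)
    elif mode == "random":
        rng = np.random.default_rng(seed)
        anc = rng.integers(0, 2, size=freq1.shape[0]).astype(np.int8)
    else:
        raise DataError(f"unknown ancestral-assignment mode {mode!r}")
    anc[mono] = -1
    return anc


def _side_ehh(hap_block: np.ndarray, carriers: np.ndarray,
              cols: np.ndarray, cutoff: float) -> tuple[np.ndarray, bool]:
    """EHH outward along ``cols``; stops after the first value below cutoff.

    Returns (values, truncated): truncated is True when the chromosome ended
    while EHH was still >= cutoff.
    """
    n = carriers.size
    tot = n * (n - 1) // 2
    labels = np.zeros(n, dtype=np.int64)
    values: list[float] = []
    for c in cols:
        key = labels * 2 + hap_block[carriers, c]
        _, labels = np.unique(key, return_inverse=True)
        cnt = np.bincount(labels)
        e = float((cnt * (cnt - 1)).sum() / 2 / tot)
        values.append(e)
        if e < cutoff:
            return np.asarray(values), False
    return np.asarray(values), True


def ehh(haps: HaplotypeSet, loci: LocusMap, focal: int, allele: int,
        ehh_cutoff: float = DEFAULT_EHH_CUTOFF) -> EHHCurve:
    """EHH decay curve for one allele at the focal SNP (global column index)."""
    chrom = str(loci.chrom[focal])
    idx = loci.chrom_indices()[chrom]
    local = int(np.flatnonzero(idx == focal)[0])
    block = haps.haplotypes[:, idx]
    carriers = np.flatnonzero(block[:, local] == allele)
    if carriers.size < 2:
        raise DataError(
            f"<2 haplotypes carry allele {allele} at {loci.name[focal]}")
    left_cols = np.arange(local - 1, -1, -1)
    right_cols = np.arange(local + 1, idx.size)
    lv, lt = _side_ehh(block, carriers, left_cols, ehh_cutoff)
    rv, rt = _side_ehh(block, carriers, right_cols, ehh_cutoff)
    pos = loci.pos[idx]
    positions = np.concatenate([pos[left_cols[:lv.size]][::-1],
                                [pos[local]], pos[right_cols[:rv.size]]])
    values = np.concatenate([lv[::-1], [1.0], rv])
    return EHHCurve(str(loci.name[focal]), int(pos[local]), int(allele),
                    positions, values, lt, rt)


def ihh(curve: EHHCurve) -> float:
    """Integrated EHH: trapezoid area over bp distance, both sides summed."""
    k = curve.focal_index
    x = curve.positions.astype(float)
    y = curve.values
    left = float(np.trapezoid(y[:k + 1][::-1], curve.focal_pos - x[:k + 1][::-1]))
    right = float(np.trapezoid(y[k:], x[k:] - curve.focal_pos))
    return left + right


def curve_reliable(curve: EHHCurve,
                   border_cutoff: float = DEFAULT_BORDER_CUTOFF) -> bool:
    """False when a side hit the chromosome end with EHH still above cutoff."""
    k = curve.focal_index
    left_end = curve.values[0] if k > 0 else 1.0
    right_end = curve.values[-1] if k < curve.values.size - 1 else 1.0
    if curve.truncated_left and left_end > border_cutoff:
        return False
    if curve.truncated_right and right_end > border_cutoff:
        return False
    return True


def compute_ihh_table(haps: HaplotypeSet, loci: LocusMap,
                      min_maf: float = 0.05,
                      ehh_cutoff: float = DEFAULT_EHH_CUTOFF,
                      border_cutoff: float = DEFAULT_BORDER_CUTOFF,
                      ) -> pd.DataFrame:
    """Per-SNP iHH for both alleles — the assignment-independent heavy step.

    One row per SNP: ``freq1`` (allele-1 frequency), ``ihh0``/``ihh1`` and
    ``analyzed`` (False when MAF < ``min_maf``, fewer than two carriers of
    either allele, or a chromosome-border truncation leaves a curve
    unreliable).  Random- and major-allele scans both reuse this table.
    """
    m = loci.n_snps
    freq1 = haps.allele_frequency()
    maf = np.minimum(freq1, 1.0 - freq1)
    ihh_by_allele = np.full((m, 2), np.nan)
    analyzed = np.zeros(m, dtype=bool)
    chrom_map = loci.chrom_indices()
    for chrom, idx in chrom_map.items():
        block = haps.haplotypes[:, idx]
        pos = loci.pos[idx]
        for local in range(idx.size):
            j = int(idx[local])
            if maf[j] < min_maf:
                continue
            ok = True
            areas = [np.nan, np.nan]
            for allele in (0, 1):
                carriers = np.flatnonzero(block[:, local] == allele)
                if carriers.size < 2:
                    ok = False
                    break
                lv, lt = _side_ehh(block, carriers,
                                   np.arange(local - 1, -1, -1), ehh_cutoff)
                rv, rt = _side_ehh(block, carriers,
                                   np.arange(local + 1, idx.size), ehh_cutoff)
                left_end = lv[-1] if lv.size else 1.0
                right_end = rv[-1] if rv.size else 1.0
                if (lt and left_end > border_cutoff) or (rt and right_end > border_cutoff):
                    ok = False
                    break
                xl = pos[local] - pos[local - 1 - np.arange(lv.size)]
                xr = pos[local + 1 + np.arange(rv.size)] - pos[local]
                area = float(np.trapezoid(np.concatenate([[1.0], lv]),
                                          np.concatenate([[0.0], xl])))
                area += float(np.trapezoid(np.concatenate([[1.0], rv]),
                                           np.concatenate([[0.0], xr])))
                areas[allele] = area
            if ok and areas[0] > 0 and areas[1] > 0:
                analyzed[j] = True
                ihh_by_allele[j] = areas
    return pd.DataFrame({
        "chrom": loci.chrom, "name": loci.name, "pos": loci.pos,
        "freq1": freq1, "ihh0": ihh_by_allele[:, 0],
        "ihh1": ihh_by_allele[:, 1], "analyzed": analyzed,
    })


def standardize_ihs(u: np.ndarray, daf: np.ndarray, bin_width: float = 0.05,
                    min_bin: int = 10, return_bins: bool = False):
    """Standardize within derived-allele-frequency bins to mean 0 / SD 1.

    Bins of width ``bin_width`` over (0, 1); bins holding fewer than
    ``min_bin`` scores are merged with their nearest neighbouring bin.
    NaN scores pass through untouched.  With ``return_bins`` also returns
    the merged-group id per SNP (-1 for unscored SNPs).
    """
    u = np.asarray(u, dtype=float)
    daf = np.asarray(daf, dtype=float)
    ok = ~np.isnan(u)
    if not ok.any():
        raise DataError("no scores to standardize")
    n_bins = int(np.ceil(1.0 / bin_width))
    # epsilon guards the bin edge: daf = k*bin_width belongs to bin k
    bin_id = np.minimum(np.floor(np.nan_to_num(daf) / bin_width + 1e-9).astype(int),
                        n_bins - 1)

    counts = np.bincount(bin_id[ok], minlength=n_bins)
    groups: list[list[int]] = [[b] for b in range(n_bins) if counts[b] > 0]
    def gcount(g): return int(counts[g].sum())
    while len(groups) > 1:
        sizes = [gcount(np.asarray(g)) for g in groups]
        small = [i for i, s in enumerate(sizes) if s < min_bin]
        if not small:
            break
        i = small[0]
        j = i - 1 if i > 0 else i + 1
        if 0 < i < len(groups) - 1 and sizes[i + 1] < sizes[i - 1]:
            j = i + 1
        merged = sorted(groups[min(i, j)] + groups[max(i, j)])
        groups[min(i, j)] = merged
        del groups[max(i, j)]

    out = np.full_like(u, np.nan)
    group_of = np.full(u.shape[0], -1, dtype=np.int64)
    for gi, g in enumerate(groups):
        mask = ok & np.isin(bin_id, g)
        if mask.sum() < 2:
            warnings.warn("frequency bin with <2 scores; left unstandardized (NaN)")
            continue
        sd = float(np.std(u[mask], ddof=1))
        if sd == 0.0:
            raise DataError("zero standard deviation in a frequency bin")
        out[mask] = (u[mask] - float(np.mean(u[mask]))) / sd
        group_of[mask] = gi
    if return_bins:
        return out, group_of
    return out


def _scores_from_table(table: pd.DataFrame, ancestral: np.ndarray,
                       ) -> tuple[np.ndarray, np.ndarray]:
    """(unstandardized score, derived allele frequency) per SNP."""
    anc = np.asarray(ancestral)
    ihh0 = table["ihh0"].to_numpy()
    ihh1 = table["ihh1"].to_numpy()
    freq1 = table["freq1"].to_numpy()
    analyzed = table["analyzed"].to_numpy() & (anc >= 0)
    u = np.full(len(table), np.nan)
    daf = np.full(len(table), np.nan)
    a1 = analyzed & (anc == 1)
    a0 = analyzed & (anc == 0)
    with np.errstate(invalid="ignore", divide="ignore"):
        u[a1] = np.log(ihh1[a1] / ihh0[a1])
        daf[a1] = 1.0 - freq1[a1]
        u[a0] = np.log(ihh0[a0] / ihh1[a0])
        daf[a0] = freq1[a0]
    return u, daf


def ihs_scan(haps: HaplotypeSet, loci: LocusMap, mode: str = "major_allele",
             seed: int | None = None, min_maf: float = 0.05,
             ehh_cutoff: float = DEFAULT_EHH_CUTOFF,
             border_cutoff: float = DEFAULT_BORDER_CUTOFF,
             bin_width: float = 0.05, min_bin: int = 10,
             extreme_threshold: float = DEFAULT_EXTREME_THRESHOLD,
             ihh_table: pd.DataFrame | None = None) -> pd.DataFrame:
    """Full per-SNP iHS scan under one ancestral-assignment strategy.

    Returns one row per SNP with iHH_A/iHH_D, the derived allele frequency,
    unstandardized and standardized scores, and the extreme flag.  SNPs not
    analyzable (low MAF, monomorphic, border-truncated) carry NaN.
    """
    if ihh_table is None:
        ihh_table = compute_ihh_table(haps, loci, min_maf=min_maf,
                                      ehh_cutoff=ehh_cutoff,
                                      border_cutoff=border_cutoff)
    anc = assign_ancestral(haps, mode=mode, seed=seed)
    u, daf = _scores_from_table(ihh_table, anc)
    z = standardize_ihs(u, daf, bin_width=bin_width, min_bin=min_bin)
    out = ihh_table[["chrom", "name", "pos", "freq1"]].copy()
    out["ancestral"] = anc
    out["daf"] = daf
    out["ihh_a"] = np.where(anc == 1, ihh_table["ihh1"], ihh_table["ihh0"])
    out["ihh_d"] = np.where(anc == 1, ihh_table["ihh0"], ihh_table["ihh1"])
    out.loc[np.isnan(u), ["ihh_a", "ihh_d"]] = np.nan
    out["u"] = u
    out["ihs"] = z
    out["abs_ihs"] = np.abs(z)
    return call_extreme(out, threshold=extreme_threshold)


def call_extreme(results: pd.DataFrame,
                 threshold: float = DEFAULT_EXTREME_THRESHOLD) -> pd.DataFrame:
    """Flag SNPs with |iHS| strictly greater than the threshold."""
    out = results.copy()
    out["extreme"] = out["abs_ihs"].to_numpy() > threshold
    return out


@dataclass
class RandomReplicateResult:
    """Aggregate of repeated random ancestral assignments."""

    summary: pd.DataFrame          # per SNP: mean/sd of |iHS| across replicates
    replicates: pd.DataFrame       # n_snps x n_reps standardized iHS
    rank_correlation: float        # Spearman rho of mean |iHS| vs major-allele |iHS|


def run_random_replicates(haps: HaplotypeSet, loci: LocusMap,
                          n_reps: int = 100, seed: int = 0,
                          extreme_threshold: float = DEFAULT_EXTREME_THRESHOLD,
                          ihh_table: pd.DataFrame | None = None,
                          **scan_kwargs) -> RandomReplicateResult:
    """Random-assignment iHS: ``n_reps`` fair-coin assignments, aggregated.

    The expensive iHH table is computed once and shared by all replicates.
    Per SNP the mean and SD of |iHS| over replicates are reported, with the
    extreme flag applied to the mean; the Spearman rank correlation against
    the major-allele-mode |iHS| is the agreement diagnostic between the two
    assignment strategies.
    """
    if ihh_table is None:
        ihh_table = compute_ihh_table(
            haps, loci,
            min_maf=scan_kwargs.get("min_maf", 0.05),
            ehh_cutoff=scan_kwargs.get("ehh_cutoff", DEFAULT_EHH_CUTOFF),
            border_cutoff=scan_kwargs.get("border_cutoff", DEFAULT_BORDER_CUTOFF))
    bin_width = scan_kwargs.get("bin_width", 0.05)
    min_bin = scan_kwargs.get("min_bin", 10)
    rng = np.random.default_rng(seed)
    cols = {}
    for r in range(n_reps):
        anc = assign_ancestral(haps, mode="random",
                               seed=int(rng.integers(0, 2**31 - 1)))
        u, daf = _scores_from_table(ihh_table, anc)
        cols[f"rep{r}"] = standardize_ihs(u, daf, bin_width=bin_width,
                                          min_bin=min_bin)
    reps = pd.DataFrame(cols, index=ihh_table["name"])
    mean_abs = reps.abs().mean(axis=1)
    sd_abs = reps.abs().std(axis=1, ddof=1) if n_reps > 1 else np.nan

    major = ihs_scan(haps, loci, mode="major_allele", ihh_table=ihh_table,
                     extreme_threshold=extreme_threshold, **scan_kwargs)
    summary = major[["chrom", "name", "pos", "daf"]].copy()
    summary["mean_abs_ihs"] = mean_abs.to_numpy()
    summary["sd_abs_ihs"] = np.asarray(sd_abs) if n_reps > 1 else np.nan
    summary["abs_ihs"] = summary["mean_abs_ihs"]
    summary = call_extreme(summary, threshold=extreme_threshold)

    both = (~major["abs_ihs"].isna()) & (~mean_abs.isna().to_numpy())
    rho = float("nan")
    if both.sum() >= 3:
        rho = float(stats.spearmanr(major.loc[both, "abs_ihs"],
                                    mean_abs.to_numpy()[both]).statistic)
    return RandomReplicateResult(summary, reps, rho)
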