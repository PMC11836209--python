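# Methods

## Scope and data model

sweepscan analyzes one population of diploid individuals typed on a
medium-density SNP array. Three containers carry the data: a `LocusMap`
(chromosome, 1-based bp position, allele labels; positions strictly
increasing within a chromosome), a `GenotypeMatrix` (0/1/2 counts of
`allele_b`, −1 missing) for QC, diversity and ROH, and a `HaplotypeSet`
(phased binary matrix, two rows per individual, no missing values) for
EHH/iHS. Phasing and imputation are preconditions, not package
responsibilities: an unphased VCF is rejected with a pointer to external
phasing tools. All internal intervals are 1-based closed; BED input/output
converts to and from 0-based half-open in one tested place.

## Quality control

Filters are applied in a fixed order: non-autosomal loci (default autosome
set: sheep, chromosomes 1–26, configurable), samples with call rate < 0.90
(computed on autosomal loci), SNPs with call rate < 0.90, SNPs with
MAF < 0.05 recomputed on retained samples. Sample filtering precedes the
frequency-dependent SNP filters, matching common PLINK practice; the report
is additive by construction (each SNP/sample removed exactly once, in
order) and the filter is idempotent. MAF uses non-missing calls only.

## Diversity and inbreeding

He carries the small-sample correction 2p(1−p)·n/(n−1) with n the
non-missing diploid count, and F_HOM's expected-homozygosity term E uses
the same convention, so the two statistics are mutually consistent (the
PLINK `--het` convention). Whether a given published table used the
correction is usually unstated; at array sample sizes the difference is
below the reporting precision, and simulation tests assert agreement with
tolerances rather than exact equality. Pairwise IBS uses pairwise deletion
(loci complete in both individuals); reported spreads are sample SDs
(ddof 1). MAF class edges: the first class is closed [0, 0.01], the rest
half-open (lo, hi], so every MAF maps to exactly one of the seven classes.

## ROH detection

The scanner implements sliding-window semantics (the detectRUNS-style
method): a window of `min_snps` SNPs moves one SNP at a time; windows with
≤ 1 heterozygous and ≤ 2 missing calls are hits; a SNP is a run candidate
when hits / covering-windows exceeds `window_hit_proportion` (default 0.05,
the detectRUNS default — not derivable from first principles, so it is
configurable). Maximal candidate stretches are split at inter-SNP gaps
> 1 Mb (the gap rule bounds gaps *within* runs; runs are never merged
across a gap) and kept only if they hold ≥ `min_snps` SNPs, span ≥ 1 Mb and
have ≥ 1 SNP/100 kb. Heterozygous or missing SNPs inside a run are
permitted exactly when the per-window rule admits them. Window size
defaults to the false-positive bound L = ⌈ln(a/(n_s·n_i))/ln(1−het)⌉
(ceiling, which guarantees the bound; at study scale — 45,943 SNPs, 514
individuals, het 0.388, a = 0.05 — the raw value is 40.68 and L = 41).
Run length is end − start + 1 over SNP positions, and L_genome sums
(last − first + 1) per autosome, so a run covering a whole mapped
chromosome yields F_ROH exactly 1. Length classes are half-open
[1,5), [5,10), [10,20), [20,40), [40,∞) Mb. The island threshold is
inclusive (incidence ≥ 0.10). The scanner is verified segment-for-segment
against a loop-by-loop oracle on random fixtures.

## EHH / iHS

EHH is computed by iterative refinement of haplotype-group labels among
carrier haplotypes, which is exactly the pairwise-identity definition (the
test suite checks equality against direct pair enumeration). Each side
extends until EHH < 0.05 (that boundary point is kept for integration) or
the chromosome ends; a side ending with EHH still > 0.10 marks the SNP
unreliable and excludes it from standardization — the rehh-style border
rule. Integration is trapezoid over physical bp; no genetic map is assumed
on array data. SNPs with MAF < 0.05 or fewer than two carriers of either
allele are not scored.

Standardization is performed within derived-allele-frequency bins of width
0.05 (bins under 10 SNPs merge with their nearest neighbour): the score
formula nominally uses global moments, but unbinned standardization
confounds iHS with allele frequency, and the binned form is the standard
practice of the method's reference implementations. The per-bin mean-0/SD-1
contract is asserted to 1e-9.

Ancestral states: `major_allele` mode takes the higher-frequency allele
(an exact 0.5 tie deterministically resolves to allele 0); `random` mode
draws a fair coin per SNP. Repeated random assignment reuses the per-allele
iHH table (EHH does not depend on the assignment; only the sign of
ln(iHH_A/iHH_D) and the frequency bin do), reports the per-SNP mean and SD
of |iHS| across replicates, and a Spearman rank correlation against the
major-allele scan as the mode-agreement diagnostic. How to best collapse
many random replicates into one call is genuinely open; the mean-|iHS|
summary plus diagnostic was chosen over any hidden consensus rule.

Region calling tiles each chromosome into non-overlapping 500-kb windows
anchored at position 1 ([k·size+1, (k+1)·size], assembly-aligned rather
than data-dependent); a window with ≥ 10 analyzed SNPs of which ≥ 5 are
extreme (|iHS| > 3.2, strict) is called, and adjacent called windows merge.
"10 SNPs" is read as a minimum: fixed windows on an array hold variable
SNP counts, so an exact-count rule would be arbitrary.

## Synthetic data

The generator emulates the study design — a few hundred individuals at
~50K-array density — not a demographic history. Neutral haplotypes come
from a two-pool hidden-Markov model: per-SNP population frequencies from a
U-shaped Beta(0.5, 0.5) spectrum (clipped at the MAF floor, default 0.05 to
emulate post-QC data); each haplotype follows a two-state Markov chain
(switch probability 0.05 per adjacent SNP) between pool-specific
frequencies f ± 0.8·min(f, 1−f), giving local LD that decays over roughly
1 Mb at default spacing. Realized column MAFs below the floor are lifted by
flipping randomly chosen majority-allele copies. Positions are uniform
draws, sorted, 1-based.

Sweeps copy one donor haplotype into exactly round(freq·n_hap) carriers
over a ± flank, with copy fidelity decaying linearly from 1 at the focal
SNP to 0 at the flank edge (the simplest shape producing monotone EHH
decay). The focal column is recoded so the derived allele marks carriers
exactly; no entry outside the flank changes. Autozygous tracts overwrite
the second parental haplotype with the first inside the tract; genotypes
are the sum of the two haplotypes, with optional uniform missingness that
by default avoids truth tracts (so recovery tests measure the detector, not
the missingness process). Everything is bit-reproducible from seeds.

What the generator does *not* emulate: genotyping error, array
ascertainment bias beyond the MAF floor, realistic recombination maps,
demography (bottlenecks, admixture) and background relatedness. Passing
recovery tests therefore demonstrate method correctness under clean
conditions, not robustness to confounded real data — demographic events can
mimic sweeps, and that caveat applies to any within-population scan.

## Problem sizes and numerical choices

Validation uses fixtures the method can resolve at desk scale: EHH oracle
checks on ≤ 20 haplotypes × ≤ 50 SNPs (200 fixtures), ROH oracle checks on
≤ 300 SNPs (50 fixtures), neutral iHS calibration and sweep recovery on
200 haplotypes × 5,000 SNPs over 100 Mb (5 seeds each; sweep frequency 0.5,
2-Mb flank; 20 random-assignment replicates), inbreeding coherence on 60
individuals × 4,000 SNPs with planted autozygosity levels 0–30 %. Bin-edge
assignment in frequency binning uses a 1e-9 epsilon so daf = k·0.05 lands
in bin k despite floating-point division; the minimum-SNP bound uses a
ceiling; extreme calling is strictly greater than 3.2; the island threshold
is ≥ 0.10.

## Known limitations

Pairwise IBS is O(n²·m) and intended for cohort-scale diagnostics, not
biobank data. Binary PLINK BED, cross-population statistics (XP-EHH, nSL,
F_ST), gene-set enrichment and QTL-database retrieval are out of scope;
annotation is a generic BED interval overlap. The CLI writes TSV tables
sufficient for Manhattan-style plots but does not render figures.
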