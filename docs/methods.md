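# Methods

## The FPVD scan

For a hybrid set of size n and a biallelic site, each hybrid contributes an
indicator d that is 1 when its two parents carry different genotype calls and
0 when they carry the same call; FPVD = Σd / n.  Genotypes are allele-dosage
codes {0, 1, 2} with a distinct missing code.  Two treatments of hybrids with
a missing parental call are exposed, because the plain formula does not
address missingness:

- `informative` (default): uninformative hybrids are excluded from numerator
  and denominator.  This is unbiased for the pair-difference probability.
- `literal`: divide by total n with uninformative d = 0, which reproduces the
  formula verbatim but deflates FPVD in proportion to missingness.

Sites where fewer than `min_informative_frac` (default 0.8, mirroring the
site call-rate filter) of the hybrids are informative are reported as
undefined and never seed loci.  Heterozygous parent calls are compared as
codes, so a het differs from either homozygote; the parents are inbred
breeding lines, so hets are rare (residual rate ~1%) and a het parent
transmits a differing gamete half the time.  This is the simplest consistent
rule; a sensitivity analysis can rerun the scan with hets masked to missing.

SNPs and indels are scanned independently.  Loci are called on the SNP track
(the denser, better-behaved class); per-locus counts then include
cutoff-exceeding sites of both classes inside the merged interval.

## The simulated inferior null and the cut-off

All restorer × sterile pairs minus the real superior pairs form the
simulated inferior set (for the 3-line system, restorers = 3R and steriles =
CMS; for 2-line, restorers = 3R ∪ 2R and steriles = GMS).  Pair exclusion is
unordered so pedigree files that store the cross in either direction are
handled identically.  Known sterility/fertility genes must differ between the
parents of every cross in either set, so their peaks bound any sensible
cut-off from below: the calibration report takes the peak FPVD inside each
known-gene interval and recommends the minimum peak rounded *down* to two
decimals (never below a 0.5 floor), guaranteeing the recommendation does not
exceed any control peak.  The default scan cut-off is 0.9, non-strict
(fpvd ≥ 0.9).

## Locus windows

Each qualifying SNP seeds the interval [pos − 50 kb, pos + 50 kb), clipped at
chromosome edges (clipped loci are flagged and may be shorter than 100 kb).
Overlapping *and* book-ended intervals merge: two sites exactly 100 kb apart
describe one contiguous candidate region.  Coordinates are 0-based half-open
internally and in BED output; VCF positions are 1-based.

## Site filters

Mirroring a vcftools pass: per-genotype GQ < 5 set to missing at VCF read
time when the FORMAT block carries GQ (minimal VCFs without GQ are read
as-is); sites kept when call rate ≥ 0.8 and minor allele frequency, computed
on called alleles only, is strictly greater than 0.01 (ties at exactly 0.01
are removed).

## Relatedness

IBS distance: 1 − mean over co-called sites of (2 − |g_i − g_j|)/2 on dosage
codes; a metric on complete data.  Kinship: dosages imputed to the site mean,
mean-centered, K = WW′/m over m polymorphic sites (the centered estimator;
a standardized variant divides each site by its dosage standard deviation —
the cut-off convention of 0.45, 10% below the first-degree value 0.5, was
defined for the centered type, which is the default).  Relationships are
coefficients strictly above the threshold; clusters are connected components
with ≥ 2 members.  Subgroup classification is a two-reference
nearest-neighbour rule on IBS distance to a typical IndI and a typical IndII
anchor accession, with a 0.02 tie band below which accessions stay
unassigned — a deliberately simple stand-in for model-based structure
estimation, adequate because the two indica subgroups are strongly diverged.

## F_st sweep cross-check

Per-site Weir–Cockerham (1984) two-population components with the
heterozygosity correction; windows (10 kb, step 10 kb, tiling) combine sites
as the ratio of summed numerators to summed denominators.  Negative window
values are reported as computed, with a clipped [0, 1] display column.
Windows at or above the (1 − 0.01) quantile of non-empty windows are flagged
(ties all flagged — deterministic), and adjacent flagged windows merge into
sweep regions.  Because F_st compares the two parental *populations* rather
than the parent pairs of specific superior hybrids, it is a cross-check for
FPVD peaks, not a replacement.

## Gene PAV

Covered fraction = bases with depth strictly > 2 ÷ gene length, positions
absent from the (sparse) depth track counting as depth 0.  Calls: absent if
≤ 0.05, present if ≥ 0.95, else partial — the underlying study criterion is
"completely absent", which leaves the exact boundary open; these defaults
tolerate a handful of stray reads and are configurable.  Runs of ≥ 2
consecutive absent genes on one chromosome flag a candidate large deletion
spanning the first gene's start to the last gene's end.

## The synthetic generator

Emulates the structure of a ~1,100-accession parental resequencing panel at
a scale that runs in seconds: two diverged subgroups (IndI-like, IndII-like)
of near-fully inbred accessions; roles CMS/GMS/3R/2R/3M/CR/GR with CMS lines
mostly IndI and restorers mostly IndII; superior pairings concentrated on
IndII-restorer × IndI-sterile crosses (weight 0.90 by default, matching the
strong skew seen in real crossing patterns).

Subgroup allele frequencies follow a Balding–Nichols perturbation of a
shared ancestral frequency (Beta with F = `subgroup_divergence`, default
0.3, the scale of divergence between the two indica subgroups), which gives
tunable background F_st and background FPVD.  Genotypes are homozygous draws
with a residual het rate of 0.01 and missing calls at rate 0.02.

Planted truth: (1) heterosis sites — every female parent of the target
hybrid set is set hom-ref and a subset of male parents chosen by an exact
subset-sum over their hybrid counts is set hom-alt, so the realized fraction
of differing pairs equals the target FPVD within 1/n; (2) one
sterility/fertility site fixed hom-ref in sterile lines and hom-alt in
restorers (spared from missingness injection so its fixation is exact);
(3) a 408-kb deletion on the last chromosome carried by two CMS accessions
and containing four genes, visible as zero depth in the deleted accessions'
tracks (elsewhere depth is base 17 with ±2 jitter, bounded so non-deleted
genes are always fully covered).

What the generator does **not** emulate: linkage disequilibrium and
recombination (sites are independent draws), pedigree-realistic breeding
histories (accessions are unrelated, so kinship clustering correctly finds
no clusters on default panels), allele-frequency spectra shaped by
selection, and sequencing artifacts beyond uniform missingness.  Passing
tests therefore demonstrate the correctness of the statistics and the
recovery of planted signals under realistic divergence and noise levels, not
performance under LD or cryptic relatedness.

## Default scales and runtime

Default synthetic scale: 2 chromosomes × 5 Mb, 20,000 SNPs + 2,000 indels,
120 accessions, 40 + 15 superior hybrids; the full eight-stage pipeline runs
in ~5 s on one CPU.  Tests use panels from a few sites up to this scale;
oracle-equivalence checks run at ≤ 100 sites × ≤ 50 hybrids (FPVD) and
≤ 1,000 intervals (merging), where exhaustive brute force is exact and fast.
The acceptance script uses a 1 × 5 Mb, 2,000-SNP panel with 100 hybrids for
the locus-length measurement and a 20 × 20 fixed-difference panel (400
inferior crosses) for the null-set FPVD measurement.

## Numerical and design notes

- All randomness flows through `numpy.random.default_rng` seeded per stage;
  identical configuration + seed reproduces byte-identical outputs.
- FPVD computation is chunked over hybrids (4,096 rows at a time), so
  simulated inferior sets of tens of thousands of crosses stay in memory.
- IBS and reference-distance computations use genotype-class indicator
  matrix products — exact, no sampling.
- Degenerate inputs: empty hybrid sets, monomorphic-only panels, inverted
  intervals, unknown sites, overlapping populations and infeasible pair
  requests all raise typed errors naming the offending value.
- The 2-line inferior set uses restorers = 3R ∪ 2R, since both restorer
  classes are crossed to GMS lines in practice.
- Known limitation: locus calling assumes dense enough SNP tracks that a
  true signal region contains at least one qualifying SNP; a signal carried
  only by indels would be missed under the default calling class.
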