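# Methods

## Scope and data model

The package analyses a multi-sample VCF of biallelic autosomal SNPs. All
stages operate on one in-memory container, `GenotypeMatrix`: per chromosome,
strictly increasing 1-based positions and a sites × samples array of genotype
codes (0 hom-ref, 1 het, 2 hom-alt, −1 missing). Upstream read processing,
alignment and variant calling are out of scope; the VCF is the interface.
Multiallelic and non-SNP records are skipped on read.

## Site filtering

A site is removed when its minor allele frequency (computed over non-missing
alleles) is strictly below `maf_min` (default 0.05) or its missing-call
proportion strictly exceeds `max_missing` (default 0.05, i.e. a 95 % call-rate
rule). One configurable pass is implemented: where a second, looser pass
(call rate 0.8 / missingness 0.2) is applied in practice, it is a no-op after
the stricter pair, so only the dominating thresholds are exposed. The
boundary semantics keep a site whose MAF equals the threshold exactly
(removal is "less than"), which the tests pin down.

Filtering interacts with the sweep scan: the SFS factor counts rare alleles,
and a MAF ≥ 0.05 filter removes singletons entirely in large samples. The
scan therefore defaults to running on the unfiltered matrix
(`filter_before_scan: false` in the pipeline config; `--filter` on the CLI
opts in), and the SFS class bound `sfs_class_k` is exposed.

## Composite µ-statistic

For each sliding window of `window_snps` (*W*, default 50, required even)
consecutive SNPs:

* **µ_VAR** = (pos_last − pos_first) / chromosome length. A fixed SNP count
  spanning more sequence indicates locally reduced diversity. Chromosome
  lengths come from the VCF `##contig` headers (falling back to the last SNP
  position).
* **µ_SFS** = c/W where c counts window sites whose folded minor-allele
  count over non-missing alleles is ≤ `sfs_class_k` (default 1). Folded
  counts are used because a single VCF provides no ancestral polarization.
* **µ_LD** = ((R_L + R_R)/2) / (R_X + ε), where R_L and R_R are the mean
  pairwise r² within the left and right half-windows (split at W/2 by SNP
  index) and R_X the mean r² of cross-half pairs; ε (default 1e-9) guards
  the division. r² is computed on unphased genotype dosages with pairwise
  deletion of missing calls; pairs where either site is constant over the
  jointly called samples carry no information and are excluded from the
  means. r² additionally uses only *informative* sites — segregating with
  minor count > `sfs_class_k`. Rare-variant r² estimates are dominated by
  sampling noise, and a sweep's planted singleton excess would otherwise
  leak into (and degrade) the LD contrast; a frequency floor before LD
  estimation is the standard remedy. Windows with fewer than
  `min_segregating` (default 2) informative sites in either half are
  skipped, not scored.

µ = µ_VAR · µ_SFS · µ_LD; the scan emits one scored window per SNP offset.
The factor formulas are fixed by this package to realize the three signals on
unphased genotypes; numerical agreement with any particular sweep-scan tool's
internal normalization is not a goal — detection of planted sweeps is, and is
what the tests verify.

## Two-step percentile selection

Per chromosome: stage 1 keeps the windows whose µ reaches the k-th largest
score with k = ⌈`top_fraction` · n⌉ (default 1 %); stage 2 keeps, within the
stage-1 subset of the same chromosome, windows at or above the nearest-rank
`inner_percentile` quantile (default 99.99). Ties at either cutoff are kept.
Nearest-rank (ceiling) quantiles need no interpolation rule and reproduce
identically across platforms; a sort-and-slice oracle checks equivalence on
random inputs, including the all-ties case. Retained windows overlapping in
bp merge into candidate regions carrying the maximum µ as peak score. Both
stage-1 ("raw") and stage-2 ("filtered") outputs are reported, since summary
tables conventionally show both.

## ROH calling

Per sample and chromosome: (1) every window of `window_snps` (50) consecutive
sites is homozygous iff it contains at most `window_het_max` (2) heterozygous
and `window_missing_max` (10) missing calls; (2) each SNP's hit proportion is
homozygous windows covering it over windows covering it — only full windows
are evaluated, so SNPs near chromosome ends are covered by fewer windows and
their denominator shrinks accordingly (no padding convention needed);
(3) SNPs with hit proportion ≥ `hit_proportion_min` (0.025) form maximal
consecutive runs; (4) runs split where adjacent run SNPs lie more than
`max_gap_kb` (1000) apart; (5) a run is reported iff length ≥ `min_length_kb`
(500), SNPs ≥ `min_snps` (50) and kb-per-SNP ≤ `density_kb_per_snp_max`
(500). Segment coordinates are first-to-last SNP; length = end − start + 1.
The 2.5 % proportion is interpreted as the per-SNP hit-proportion threshold —
the only proportion parameter in this windowed procedure; a per-region
reading is conceivable but not implemented.

The defaults are WGS-tuned: length and SNP-count minima halved relative to
array-era conventions (500 kb / 50 SNPs vs 1000 kb / 100 SNPs) to retain
segments in SNP-sparse or unevenly covered regions, and window tolerances and
density relaxed (2 het / 10 missing / 500 kb-per-SNP vs 1 / 5 / 50) to absorb
the higher marker density, residual genotyping error and reference bias of
short-read data from admixed indicine populations. The array-era comparator
set ships as `ARRAY_DEFAULT_PARAMS`, and `froh_concordance` quantifies
rank (Spearman) and linear (Pearson) agreement of per-sample F_ROH between
the two parameterizations.

An exhaustive brute-force implementation of steps (1)–(5) lives in the test
suite and is checked against the vectorized caller on hundreds of randomized
instances and parameter sets.

## F_ROH and conserved ROH

F_ROH = Σ segment length / `l_auto_kb`. The default constant,
2,489,385.779 kb, is the autosomal span covered by the SNPs of the motivating
95-animal cattle panel; the pipeline substitutes the span of the analyzed
SNPs when no constant is supplied.

Per-SNP incidence counts the individuals carrying each analyzed SNP inside at
least one ROH (an individual counts once per SNP, however many segments cover
it); incidence is computed on the same filtered site list used for calling.
The conserved-ROH cutoff is ⌈`threshold_prop` · N⌉ — the ceiling makes "at
least the breed-specific proportion" an attainable integer count. Maximal
runs of consecutive retained SNPs (no intervening non-retained SNP on the
chromosome's site list) become conserved regions; all segments overlapping a
region's retained SNPs are recovered as contributing segments, over which
count/mean/SD summaries are computed. Threshold proportions are supplied per
population (values near 0.45–0.6 are typical); no rule derives them from
sample size, so they are configuration, not code. ROH are deliberately not
stratified by length class: the target is conserved regions, not inbreeding
age.

## Annotation

Interval arithmetic is 1-based inclusive throughout (the native convention of
GTF and of QTL-database exports); BED's 0-based half-open convention applies
only at file boundaries. A candidate region is retained when some gene
overlaps it by ≥ 50,000 bp, evaluated pairwise per gene; a hit is *novel*
iff the gene record lacks a `gene_name` attribute (biotype is not consulted).
QTL overlap uses ≥ 1 bp — no minimum is conventional for QTL joins, unlike
the 50 kb gene rule. Overlapping QTL records are deduplicated by identifier,
reduced to unique trait names, and counted under the six-class trait
hierarchy; the trait-name → class mapping ships as an editable text table so
class assignments are data, not code. Functional enrichment, homology search
and assembly liftover are out of scope.

## Synthetic genomes

The generator plants the exact signals the detectors look for, at desk scale,
without simulating genealogies — the methods need signals, not coalescent
realism.

* **Background.** Each chromosome has `founder_haplotypes` (P, default 20)
  founder haplotypes. SNP positions are a Poisson process at `snp_density`
  (default 2 × 10⁻³/bp, a desk-scale stand-in for the ~9 × 10⁻³/bp of a
  jointly genotyped WGS cattle panel). Derived counts over the pool follow
  the discretized neutral SFS (P(i) ∝ 1/i), so the folded background
  spectrum is ≈ 1/f — verified by a chi-square goodness-of-fit test at
  α = 0.001 on ≥ 10,000 SNPs. Each individual's two haplotypes are founder
  mosaics with Poisson switch points (mean spacing `mosaic_block_bp`,
  100 kb), giving LD that decays with distance; whole-chromosome founder
  copies would saturate LD genome-wide and per-site draws would leave none.
* **Sweeps.** Within ± `footprint` of the center: sites survive i.i.d. with
  probability `diversity_reduction`; if `ld_block`, each flank's dosage
  columns are rewritten from at most two flank haplotypes (within-flank
  r² = 1, cross-flank low); finally an `sfs_skew` fraction of surviving
  footprint sites is rewritten to minor-allele-count 1. The singleton
  rewrite runs last so the planted rare-allele excess survives; the LD
  factor's frequency floor keeps it from eroding the planted LD contrast.
* **Autozygosity.** Carriers' heterozygous calls inside the tract are
  rewritten to a homozygous state (emulating one haplotype replaced by a
  copy of the other); non-carriers are untouched. Missing calls are applied
  i.i.d. per call *after* planting, so tracts still exercise the caller's
  missing tolerance.
* **Determinism.** One master seed; per-chromosome substreams are keyed by
  (seed, crc32(chromosome name), purpose tag), so outputs are bit-identical
  across runs and stable under chromosome subsetting. Unphased diploid
  genotypes are exported (VCF 4.2, GT only); haplotypes survive only in the
  in-memory truth record.

What the generator does **not** emulate: recombination-rate variation,
demographic history, linked selection, genotyping-error structure, phasing.
Passing tests therefore demonstrate algorithmic correctness and detection of
idealized signals, not calibrated power on real data.

## Verification scales and observed behavior

Tests and the acceptance script run at desk scale: 1 Mb chromosomes with
~2,000 SNPs and 20 diploids for sweep localization (20 replicates); a 10 Mb
chromosome for F_ROH recovery (tract fractions 5 % and 25 %, 10 replicates);
10 individuals with a 6-carrier tract for conserved-ROH thresholds
(reported at 0.5, absent at 0.7). Localization requires the argmax-µ window
center within 100 kb of the planted center. F_ROH recovery is asserted within
±20 % relative error per replicate: the lenient 2.5 % hit threshold extends
segments slightly past tract edges (a few covering windows suffice), and a
5 % fraction on 10 Mb is a single 500-kb tract sitting exactly at the
caller's minimum length, so edge effects are proportionally largest there —
the acceptance script reports both mean and maximum relative error.

## Fixture tables

Two shipped TSVs transcribe per-breed summary statistics of a published
six-population Ugandan cattle WGS panel (95 animals): per-breed sweep-region
and gene counts, and ROH counts, SNPs-in-ROH, F_ROH moments, breed sharing
thresholds, conserved segments and candidate genes. Aggregating them through
`report.aggregate` reproduces the panel's printed totals (201,431 raw
regions; 895 filtered; 803 known / 92 novel genes; 13,690 ROH; 37,267,246
SNPs in ROH; 108 conserved segments; 49 candidate genes) and percentages
(0.4 %, 10.3 %, 30.6 %) under the package-wide rounding rule: percentages are
half-up rounded to one decimal via `decimal.Decimal` (binary-float rounding
would misprint exact halves like 6.25 %). The per-breed "SNPs in ROH (%)"
column is carried as data but its denominator is dataset-specific and must be
declared by the user; it is not recomputed.

## Numerical and degenerate-input choices

* MAF denominators exclude missing alleles; sites with no calls get MAF 0.
* Windows whose LD precondition fails are omitted and logged, keeping
  µ well-defined everywhere it is reported.
* Zero-variance correlation inputs return NaN (undefined) rather than
  raising, with a logged warning.
* Empty carrier lists and tracts or footprints containing no SNPs are
  warned no-ops; chromosomes with fewer SNPs than one window are skipped
  with a log entry; a chromosome simulating zero SNPs is reported degenerate.
* Per-sample ROH segments are non-overlapping and sorted by construction
  (runs are disjoint site-index intervals).
* The pipeline writes a machine-readable manifest (inputs, parameters, stage
  timings) per run and logs to standard error; reruns on identical inputs are
  byte-identical.
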