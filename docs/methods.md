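# Methods

This note documents the statistical model behind `poolscan`, the defaults and
the reasoning behind them, what the synthetic-data generator does and does not
emulate, and the numerical decisions taken where more than one reasonable
convention exists.

## Data model and assumptions

The unit of observation is a *pool*: one sequencing library from the pooled
DNA of n diploid individuals of a population. At a bi-allelic SNP the data per
pool are reference and alternative read counts; the pool allele frequency is
estimated as alt / (ref + alt). Zero-depth frequencies are *undefined* (NaN),
never 0.0, because 0.0 is a legitimate frequency.

Assumptions inherited by every downstream statistic:

- sites are bi-allelic SNPs (multi-allelic records are dropped at VCF input by
  default; an optional split mode emits one row per alternative allele);
- reads at a site are independent draws from the pool's allele frequency, so
  read counts can serve as allele-count samples;
- coordinates are 1-based at I/O boundaries (VCF, window labels) and 0-based
  half-open internally (window assignment, gene overlap, region containment).

## Variant quality control

Step 1 applies hard site filters, each bound inclusive:

| parameter | default | meaning |
|---|---|---|
| `rd_min` | 10 reads | minimum depth in *every* pool |
| `rd_max` | 68 reads | maximum depth in every pool, from `round(RD_mean + 4·√RD_mean)` at RD_mean = 42 (Li's heuristic against collapsed repeats) |
| `min_alt_reads_total` | 3 reads | minimum alternative reads summed across pools |
| `excluded_flags` | low-quality region, strand bias | caller-provided site flags |
| `excluded_chroms` | empty | blocklist for sex chromosomes / mitochondrion (assembly-specific names, so not hard-coded) |

Removal counts are attributed to the *first* failing rule in a fixed order
(chromosome, bi-allelic, rd_min, alt reads, rd_max, flags) so that reports are
deterministic and removals + survivors always equal the input count. The
filter is idempotent.

Step 2 chooses the caller quality cutoff. Variants are partitioned into
catalogue-known vs. novel and rare vs. common, where *rare* means panel-wide
minor allele frequency strictly below 1/(ploidy·n) — 1/70 ≈ 0.0143 for 35
diploids, the smallest frequency a single carrier chromosome can produce. For
each candidate cutoff Q in 0..50, variants with quality ≥ Q are retained and
the two-sample Kolmogorov–Smirnov D between the retained quality distributions
of the known-rare and novel-rare classes is computed; the selected cutoff
minimises D, ties broken toward the smaller Q. The ≥ Q retention direction is
a design choice: the cutoff is the score above which novel and known rare
variants become distributionally indistinguishable. Cutoffs at which either
class empties are excluded from the argmin and reported. D is the exact ECDF
supremum (via `scipy.stats.ks_2samp`); no p-value is used.

Step 3 reports the transition/transversion ratio as a global indicator
(~2.1–2.4 expected genome-wide in mammals). No pass/fail threshold is applied.

The allele-frequency concordance check against external genotype frequencies
excludes strand-symmetric substitutions (C↔G, A↔T), whose orientation cannot
be harmonised between platforms, and sites with > 10% genotype missingness in
the pool.

## Window statistics

Windows are a deterministic 100-kb tiling with step 100 kb; the last window of
each chromosome is truncated. A SNP at 1-based position p belongs to window
⌊(p−1)/step⌋, so position 100,000 falls in the first window and 100,001 in the
second. Unplaced scaffolds are treated as short chromosomes. The window size
is a diagnostic choice: for candidate sizes 50–300 kb the count of windows
with < 10 SNPs is reported, and the scan size is taken where this count
flattens.

**H_P** uses per-SNP major/minor read counts *within the pool*; ties
(ref = alt reads) contribute equally to both sums, so no tie rule is needed
numerically. Windows with fewer than 20 SNPs, zero depth, or H_P = 0 (log2
undefined) are not retained. Percentile selection is monotone-invariant, so
raw and log2 tracks yield identical outlier sets.

**F_ST** uses read depths as the Karlsson sample sizes n. Pools provide no
individual genotypes, so reads-as-sampled-alleles is the standard pool-seq
reading; the estimator's unbiased h term then removes read-sampling noise
within pools. Under identical pool frequencies the estimator is slightly
negative (−h/(nD)), vanishing as n grows — small negative genome-wide means
are therefore expected and not clipped. Per-window values are the arithmetic
mean of defined per-SNP F (SNPs where both pools are fixed for the same allele
are skipped); Karlsson's ratio-of-sums ΣN/ΣD is available as a mode switch.
Group contrasts sum read counts into super-pools, preserving depth weighting;
an equal-pool-weight frequency-averaging mode exists for sensitivity analysis.
A contrast of two single-pool groups reduces exactly to the pairwise track.

**Outliers.** Sweeps sit in the lower tail of H_P and the upper tail of F_ST;
both are implemented as one percentile rule on the appropriate tail. The
count is k = round((1 − 99.95/100) · N_retained), computed with half-up
rounding: at 23,267 retained windows this gives 12 (0.0005 × 23,267 = 11.63),
whereas nearest-rank percentile definitions would give 11. Percentiles are
computed on retained windows only — discarded (< 20 SNP / incomputable)
windows do not influence the threshold. Ties at the threshold are broken by
genomic order so the selected set is a deterministic function of the track.

## Population structure

Genome-wide pairwise distances are means of defined per-SNP F_ST, no
windowing; C(n, 2) pairs (253 for 23 pools). Neighbour joining is delegated
to scikit-bio's Saitou–Nei implementation (exact on additive matrices, which
the tests verify against a four-point-condition oracle); negative branch
lengths are kept internally and clamped to zero only at Newick export.
Bootstrap supports resample SNP loci with replacement, rebuild matrix and tree
per replicate, and report the percentage of replicates containing each
internal-edge bipartition of the point-estimate tree.

The Mantel test correlates off-diagonal upper triangles under joint
row/column permutation of one matrix. The p-value is one-sided with the +1
convention, p = (1 + #{r_perm ≥ r_obs}) / (n_perm + 1), default n_perm =
9,999; an exact mode enumerates all label permutations for small matrices
(≤ 8 labels) and is the oracle the permutation mode is tested against.
Geographic distances are great-circle (haversine, mean Earth radius 6371 km)
rather than Euclidean on degrees, since panels can span tens of degrees of
longitude.

## Regions and downstream analyses

Outlier windows are annotated with genes overlapping the window and genes in
the ±200-kb flanks (measured from window *edges*; flanks clipped at 0 and the
chromosome end). Adjacent outlier windows merge into regions at `max_gap = 0`
by default (configurable). H_P/F_ST concordance pairs windows of the two
scans on the same chromosome with closest-edge gap strictly below 500 kb.

Enrichment is the Enrichr-style recipe: one-sided Fisher exact test per term
on the 2×2 overlap table against an explicit universe size, BH adjustment
across terms, then the reporting filter (≥ 4 overlap genes from ≥ 2 distinct
windows, adjusted p < 0.05 strict). Gene-set collections are user-supplied
files (GMT or two-column TSV); nothing is downloaded.

Deleterious variants are classified from an externally produced impact table:
stop gain, stop lost, or non-synonymous with SIFT strictly below 0.05
(missing-score nsSNPs are counted separately, never as deleterious). The
putative ancestral allele is whichever allele exceeds frequency 0.5 in the
wild pool (undetermined at exactly 0.5 or undefined AF). The frequency
contrast flags sites with AF > 0.8 on one side and < 0.2 on the other (strict,
either direction), and flagged deleterious variants are intersected with
sweep regions using half-open containment.

## Synthetic-data generator

The generator emulates the *statistical* structure the scan assumes:
ancestral allele frequencies uniform on (0.05, 0.95); per-pool frequencies
from the Balding–Nichols Beta(p(1−F)/F, (1−p)(1−F)/F) model; finite-pool
binomial sampling of 2n chromosomes; Poisson depth (42× default, 12× wild,
truncated at ≥ 1) and binomial read sampling — two-stage sampling is
deliberate, because the finite-pool stage is what makes the 1/(2n) detection
limit meaningful. Substitution types are drawn with 2.4:1 transition odds;
catalogue-flagged sites get high quality scores while novel sites are an
explicit high/low mixture so the KS cutoff has a recoverable optimum. Sweeps
force the alternative allele to ≥ 0.98 in target pools over an interval;
group loci force near-fixed opposite frequencies between group labels. The
default toy genome is three 5-Mb chromosomes plus a 300-kb scaffold (so
scaffold handling is exercised); full-genome scale is a configuration change.

What it does *not* emulate — and therefore what passing tests do not show
about real data: linkage disequilibrium (sites are independent given pool
frequencies), recombination and coalescent history, sequencing error beyond
binomial sampling, alignment artefacts, and reference bias. Planted sweeps
are idealised hard sweeps; recovery rates on real soft or incomplete sweeps
will be lower.

## Problem sizes and verification

The test-suite and acceptance-script runs use deliberately compact problem
sizes chosen to exercise every code path with comfortable statistical margins:
the default 15.3-Mb toy genome (~176k SNPs, 5 pools) for sweep recovery;
2-Mb single-chromosome panels over 10 replicates for group-contrast recovery;
400-kb two-pool panels over the drift grid {0.01, 0.05, 0.1, 0.2}; 1,000
replicates of 7-label matrices for Mantel null calibration; 50–100 random
additive trees of up to 8 taxa for NJ; exact-fraction (rational-arithmetic)
and hypergeometric oracles for the F_ST and Fisher kernels at 1e-12
tolerance. Bootstrap replicate counts in examples are reduced from the
10,000 a publication-grade analysis would use; the interface default stays
at 10,000.

## Known limitations

- Read counts as Karlsson sample sizes ignore the overdispersion introduced
  when few DNA fragments dominate a pool library; estimated chromosome counts
  (capped at 2n) could be substituted by pre-transforming the count arrays.
- The single-breed F_ST averages window values over pairs with defined
  values; a breed compared against a close relative and a distant outgroup
  weights both equally.
- The pipeline's KS cutoff stage requires both rare sub-classes to be
  non-empty; on very small panels it is skipped with a log message rather
  than guessed.
- Windows are non-overlapping; the tiling supports a smaller step than size
  for listing purposes, but SNP assignment (and hence all scans) requires
  step = size.
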