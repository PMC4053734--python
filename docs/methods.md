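# Methods

This note documents the statistical models, the numerical choices, and the
design decisions behind `chance-qc`, including what the synthetic-data
generators do and do not emulate.

## Read handling and binning

Mapped reads (BED, tagAlign, SAM, BAM, bowtie legacy output) are reduced to
their 5' position: the interval start on the + strand, end − 1 on the −
strand, in 0-based half-open coordinates (SAM/BAM 1-based POS is converted
on input). No fragment-length extension or strand shift is applied before
binning; at the default 1-kbp bin width the difference between 5'-end and
midpoint counting is negligible. Every retained alignment record counts
once — no MAPQ filter is applied by default. Reads on chromosomes absent
from the user-declared chrom-sizes table are counted, reported, and
dropped. Optional de-duplication keeps one read per (chromosome, position,
strand) key; duplicate pile-ups usually reflect PCR over-amplification.

Bins are concatenated genome-wide in chrom-sizes order for all order-
statistic computations; partial terminal bins participate as-is.

## Signal extraction scaling

With bins sorted by IP count in increasing order — ties broken stably by
genomic order, so results are deterministic — the cumulative read-fraction
curves p(α) (IP) and q(α) (Input, under the IP-induced ordering) are
compared. The divergence statistic d = max(q − p) is attained at the
separation point α\* (smallest maximizer). The scaling factor r is the
ratio of mean IP to mean Input count over the first α\* fraction of sorted
bins (the background region). Headline percentages:

- genome enriched for signal: 100·(1 − α\*);
- IP reads attributable to antibody pulldown: 100·max(0, 1 − r·N_In/N_IP),
  i.e. the IP reads in excess of the r-scaled Input-predicted background.
  The exact formula behind the original tool's pie chart is not published;
  this background-subtraction form is the documented choice here;
- differential enrichment: percentage increase of mean IP density over
  r-scaled Input density on the signal region.

When d ≤ 0 the sample is declared not enriched and both pie percentages
are reported as 0; the summary then omits enrichment estimates but still
reports FDRs.

A caveat worth knowing: α\* estimates the background/signal boundary of the
*observed* sort, in which Poisson noise mixes high-count background bins
into the signal tail. At modest fold enrichment (≈ 4×) this biases the
estimated signal-region percentage upward for small planted fractions and
slightly downward for large ones; at fold ≥ ~8 recovery of a planted
fraction is accurate to well within ±20 % relative error. The tie-break by
genomic order means the statistic is exactly permutation-invariant only
for tie-free IP tracks; with ties the effect is confined to within-tie
ordering of q and is negligible at realistic bin counts.

### Divergence test

The test's null pools the two binned count vectors and re-splits every
bin's pooled count between the channels with a multivariate hypergeometric
draw, preserving both channel totals exactly; d is recomputed per resample
and p = (1 + #{d_null ≥ d_obs}) / (1 + n_resamples). For two channels that
are genuinely replicate draws of one read distribution this conditional
re-split is the exact null, so the test is calibrated regardless of
overdispersion in the underlying coverage. Default 100 resamples
(p-value resolution 1/101), seedable.

### q-values and the failed-sample alert

Given a training table of divergence statistics from IP–Input and
Input–Input comparisons, q(d) is the fraction of Input–Input rows among
all rows with statistic ≥ d, computed per category (histone/TF ×
normal/cancer) and pooled; an empty tail gives q = 0 (the statistic
exceeds every training comparison). The failed-sample alert fires when all
five reported q-values exceed 5 %. A synthetic training table generator is
bundled (see below); users reproduce repository-trained behaviour by
supplying their own TSV (`category`, `pair_type`, `divergence_stat`).

### Depth and amplification warnings

- Input depth: warn iff q(α) < p(α) strictly for any α. The check runs
  over all α, not only small α; any strict dip triggers.
- IP depth: α₀ is the fraction of zero-IP bins. If α\* ≤ α₀ > 0 the
  separation is driven by uncovered genome; SES is recomputed with zero-IP
  bins excised and a warning issued alongside α₀.
- Amplification: taking bins densest-first, find the smallest genome
  fraction g holding ≥ 25 % of reads; warn iff g < 1 %. Applied to each
  channel independently.

## Spectral bias analysis

Each chromosome's bin-count vector is mean-padded to the next multiple of
2^L and decomposed with a decimated Haar transform; per-level detail
energies (sums of squared coefficients) are accumulated across chromosomes
and normalized to percent of their grand total. The approximation
coefficients (chromosome means) are excluded, so the report is a
percentage of *variance* per scale. Chromosomes are never concatenated —
that would inject spurious junction energy — and a chromosome contributes
only the levels its length supports. Default L = 15 levels span 1 kbp to
16.384 Mbp at 1-kbp bins. White noise halves its energy per level
(level-1 share ≈ 50 %); localized artifacts (e.g. duplicate pile-ups
spanning ~2 kbp) appear as excess observed energy at their characteristic
scale.

The comparison track is Poisson-Gamma: counts Poisson(λ), λ ~ Gamma(k, θ),
matching the observed depth (mean kθ) and spread (variance kθ(1 + θ)).
The Gamma is fitted by maximum likelihood: +0.5 is added to every bin count
first (the Gamma density is undefined at zero and Input tracks are
zero-inflated), then the profile score equation log k − ψ(k) = log(mean) −
mean(log x) is solved by Newton iteration from the closed-form
approximation start, tolerance 1e-10, at most 100 iterations; θ = mean/k.
The simulation reuses the observed per-chromosome bin layout.

## Multi-sample consensus and batch effects

Samples are depth-normalized to the mean library size and their n×n sample
covariance M computed. The combiner weights maximize w'Mw under Σw = 1;
since a convex quadratic maximized over the simplex degenerates to a
vertex, the implemented solution is the leading eigenvector of M
(Rayleigh-quotient maximizer), sign-oriented, negative components clipped,
renormalized to the simplex — the standard eigenvector multi-channel
combiner. The consensus is c_j = Σᵢ wᵢ s_ij.

Pairwise differential enrichment reuses SES with one sample as IP and
another as Input. Two numerical points matter:

- The divergence test runs on the **raw** counts of each pair. Allocation
  curves are cumulative fractions, so library-size normalization cannot
  change d or α\*; but scaling counts up and rounding would inflate the
  resampling null's apparent depth and make the test anti-conservative.
  Normalized tracks are used only for the covariance, the weights, and the
  consensus; the real-valued consensus is rounded (nearest, ties-to-even)
  where SES needs counts.
- d = max(q − p) is one-sided: it detects enrichment of the IP-role
  sample over the Input-role sample. A genuine differential pair therefore
  shows a strong entry in the orientation whose IP carries the extra
  signal and a weaker, often non-significant entry in the reverse. Both
  orientations are computed and reported; D[a][b] is zeroed (p-value
  retained) when its own orientation's test is not significant at the
  configurable 0.05 threshold.

The batch-effect report flags pairs significant in either orientation and,
given group labels, tabulates within- vs between-group significance
counts. Because each orientation tests at the nominal 5 % level, a
replicate-only design is expected to produce the occasional false flag at
that rate; the test suite asserts binomial-consistent bounds rather than
zero.

## Spot validation and panel comparison

Per candidate region, k is the number of IP 5' ends in [start, end); the
null mean λ is the Input count there scaled by the IP/Input library-size
ratio (the unscaled convention is available via `--no-depth-scale`) and
floored at 1 read to avoid a degenerate Poisson(0) null; the p-value is
the upper tail P(X ≥ k) and the fold change k/λ. A ±3-kbp promoter-window
helper builds regions around supplied TSS points.

The panel comparison merges the union peak set, computes the fractions p
(IP) and q (Input) of reads inside it with a half-read pseudocount on the
numerator and a one-read pseudocount on the denominator (keeping both
strictly inside (0, 1)), forms OR = [p/(1−p)]/[q/(1−q)], and evaluates the
normal CDF of log OR under the panel's sample mean and standard deviation
(n ≥ 3, σ > 0 required). A percentile below 5 % is reported as poor
overlap.

## Synthetic data generators

All generators take an explicit integer seed and are bit-reproducible.

- **Binned pairs**: Input ~ Poisson-Gamma(k = 2, θ = 3) — ~6 reads/kbp,
  overdispersed as real Input is; IP shares the background means with an
  s-fraction of bins multiplied f-fold before Poisson sampling (defaults
  s = 0.1, f = 10, 50k bins), so the planted enriched fraction is exactly
  100·s. A duplicate-spike rate moves that fraction of reads onto 0.5 % of
  bins to trigger the amplification rule on demand.
- **Read files**: emitted in any supported dialect with length-1 reads
  placed uniformly within bins, so binning the file reproduces the source
  coverage exactly.
- **Training tables**: Input–Input rows from null replicate pairs
  (cancer categories receive sporadic regional copy-number-like
  distortions, giving their null a heavier tail), IP–Input rows from
  planted-enrichment pairs across a fold grid.
- **Panels**: non-overlapping peaks covering ~1 % of the genome plus
  per-sample log odds from Normal(1.0, 0.5).
- **FASTQ**: uniform base composition and Phred ≈ 38 outside a planted
  artifact window (positions 22–24 by default) with elevated GC, 10 %
  uncallable bases, and Phred ≈ 18 inside.

What these do **not** emulate: mappability and GC landscapes, chromatin-
state-dependent fragmentation, copy-number structure of real cancer
genomes, paired-end fragment geometry, or adapter contamination. Passing
tests therefore demonstrate correctness of the statistics under the stated
generative models, not robustness to every artifact of real libraries.

## Problem sizes and tolerances in the test suite

Simulated checks are sized to keep the default suite around a minute:
null-calibration of the divergence test uses 500 pairs of 5k bins at 100
resamples (nominal 0.05 within three binomial standard errors);
planted-signal recovery uses 50k bins at fold 10; batch-effect designs use
20k bins (5k is underpowered for the weaker orientation); spectral
self-consistency uses 2^15 bins. Spot-check p-values are verified against
brute-force Poisson tail sums to 1e-10 for λ ≤ 50.

## Known limitations

- SES assumes a two-component (background + signal) mixture; diffuse marks
  with genome-wide enrichment violate it and depress d.
- The q-value is only as representative as the training table; the bundled
  generator is synthetic and clearly labelled as such.
- The divergence test conditions on binned counts; it does not model
  positional structure within bins.
- The consensus weighting assumes shared background structure dominates the
  covariance; a severely biased sample can attract weight for the wrong
  reason (the per-sample-vs-consensus statistics help diagnose this).
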