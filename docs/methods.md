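# Methods

## The assay in one paragraph

DNA is sequenced shallowly; each read is reduced to its chromosome and
0-based leftmost (5') aligned coordinate; reads are counted inside
biological elements (sliding windows, gene loci, whole contigs); counts are
converted to absolute copy number by comparing, element by element, against
a reference sample of known ploidy processed with the same protocol. Using
a single matched reference cancels protocol-dependent biases (GC content,
local mappability) without modelling them, which is why no GC or
mappability regression is performed anywhere in the package.

## Counting model and uncertainty

Read placement is modelled as a Poisson process with intensity proportional
to local copy number. A window's count *x* therefore carries counting
uncertainty √x, and nothing else: biological heterogeneity and operator
variability are deliberately outside the error model. All downstream
uncertainties are propagated from this single term. For the normalized copy
number CN = P·r/m (see below) the sample and reference contributions enter
in quadrature:

    σ_CN = CN · sqrt(1/x + 1/y)

The reference term 1/y is included even though a single-measurement error
model needs only √x, because every reported quantity here is a ratio of two
noisy counts and the between-sample test assumes both variances. For x = 0
the copy number is reported as 0 but the variance is computed at x = 1, so
bounds and p-values stay finite; this is a reporting convention, not a
bias correction. Bounds are 1-σ (CN ∓ σ_CN, floored at 0). P-values are
two-sided normal tails; at the ≥50-read depths where calls are made the
normal approximation to the Poisson and any Student-type correction are
negligible. P-values are clipped to [1e-300, 1] so extreme z-scores do not
underflow to an exact zero.

## Window design

To separate copy numbers a < b at two-sided significance α, require the
count difference n(b−a)/2 to exceed z*(α) times the standard error
√(n(a+b)/2), giving

    n ≥ 2 z*² (a+b) / (b−a)²

rounded **up** (granularity 10 by default; 108.28 → 110 for the canonical
2-vs-3 at α = 0.001, two-sided — a one-sided z* would give ≈96 and is not
used). The window size is genome_size·n/usable_reads, reported raw plus a
10 kb rounding. This is a design aid; profiling accepts any window/step.

Sliding windows default to 150 kb stepping 75 kb. Windows tile each
non-mitochondrial chromosome from 0 at step multiples; the final window is
extended to the chromosome end (the leftover past the last full window is
always shorter than one step), and a chromosome shorter than one window
becomes a single truncated [0, L) window. Ends are never silently dropped —
a deliberate choice so that subtelomeric windows exist and are governed by
the reference-coverage mask rather than by the tiling. Gene-locus mode uses
the locus span or, if shorter, a 60 kb interval centered on the locus
midpoint, shifted inward at chromosome edges to preserve length. A read is
assigned to every element containing its 5' coordinate (point containment,
not fractional overlap — only the 5' position is recorded), so overlapping
windows each count it.

## Mode-of-ratio normalization

After scaling by total unique reads, ratios r = (x/X)/(y/Y) are computed on
qualifying elements: autosomal, reference count ≥ `min_ref_reads` (default
50, which is also the masking threshold for calls; fewer than 20 qualifying
elements aborts normalization with a diagnostic). The mode is estimated
from a histogram with fixed bins of width 0.02 on the ratio axis starting
at 0: the maximal bin is found (ties broken toward the smaller ratio) and
the mode is the mean of the ratios lying in that bin and its two
neighbours. The estimator is deterministic, robust to heavy copy-number
tails, and biased by at most ~half a bin by grid quantization — a ≤1%
multiplicative effect on all calls at ratios near 1.

Anchoring: the modal autosomal state is *assumed* to sit at the reference
ploidy. For a genome whose most common state is not diploid (e.g. a nearly
triploid tumor), every call is scaled by the same wrong integer factor;
the profile is then correct up to that assumption, and the ploidy map
exposed by the API/CLI is the override point. The mean or median of the
ratio distribution cannot replace the mode: on any strongly multi-modal
genome they sit between peaks and no peak lands on an integer (this is
asserted as a property test on a tri-modal simulation).

Allosomes are excluded from mode estimation but are called, using the
reference ploidy map (male reference: X = Y = 1; female: X = 2, Y = 0).

## Between-sample comparison

Two profiles normalized against the same reference are compared per
element: Δ = CN_a − CN_b, σ_Δ = √(σ_a² + σ_b²), two-sided normal p-value.
Because both profiles divide by the same reference count, their errors are
positively correlated and σ_Δ overstates the true spread by a factor
√(1 + x̄/ȳ); the test is therefore *conservative* when sample and
reference depths are comparable, and exactly calibrated in the
deep-reference regime (ȳ ≫ x̄). The null-calibration test runs at a
reference ~100× deeper than the samples for this reason; at equal depths
the p < 0.001 rejection rate drops roughly to the 4.7σ normal tail. The
covariance-free formula is kept because it is the natural reading of a
t-test on independently normalized values and errs only toward fewer false
positives. Elements masked in either profile are masked in the output.

## Element assays

Mitochondrial level: the fraction of unique aligned reads on the declared
mitochondrial contig, divided by the same fraction in the reference.
Telomere level: alignment-free; a read counts once if it contains
(TTAGGG)₄ — motif and repeat count configurable — as an exact substring of
the read or its reverse complement (strand of sequencing is arbitrary; a
flag disables reverse-complement matching), with the denominator being all
reads scanned. No mismatches are tolerated and variant repeats (TGAGGG,
…) are not handled; the measure is relative repeat content, not telomere
length in kb. Both assays propagate Poisson errors on the two raw counts
exactly as in the window comparison.

The two denominators differ by construction — unique aligned reads for
mtDNA (an alignment-based measure) versus all reads scanned for telomeres
(telomeric reads do not align uniquely) — and both are configurable in the
sense that the raw counts and denominators are reported alongside the
ratio.

## Tile uniqueness

`tile_uniqueness` enumerates every length-k tile of a genome and counts
the genomic locations matching it exactly on either strand (a palindromic
tile hitting both strands of one location counts that location once; a
tile equal to its reverse complement elsewhere is ambiguous — mirroring
aligner behaviour). Tiles containing non-ACGT characters are excluded from
the denominator and reported as a separate "unsequenced" fraction. The
implementation holds a hash table of all tiles in memory and is intended
for model genomes of at most a few megabases; surveying a mammalian genome
is a job for an aligner, not this utility.

## Simulator

The simulator is the package's source of ground truth. It draws exactly
`n_reads` positions per sample: a binomial share lands uniformly on the
mitochondrial contig at the configured mtDNA rate, and the rest are
multinomial over copy-number segments with weights length × CN (sample) or
length × ploidy (reference), uniform within a segment — matching the
Poisson counting model (multinomial totals make per-window counts
underdispersed by the negligible factor 1 − w/G). FASTQ simulation emits a
binomial fraction of pure tandem (TTAGGG)ₙ arrays with random phase and
strand; background reads are random sequence rejected against containing
the motif. All streams derive from a single seed via fixed per-stream
sub-seeds.

What it does **not** emulate: fragment-length structure, GC bias,
mappability gaps, sequencing errors, duplicate reads, or contamination.
Tests passing on simulated data therefore demonstrate the statistical
machinery (normalization, calibration, recovery) under the assay's own
model assumptions — not robustness to real-library artifacts, which the
matched-reference design addresses empirically rather than by simulation.

Canonical configurations (sizes chosen to exercise the full dynamic range
at comfortably informative depths):

- `tumor_mix_config`: four 6 Mb autosomes + mitochondrial contig; segments
  at true CN {0, 1, 2, 3, 4, 5, 12, 25, 29} with a diploid majority (106 of
  160 non-overlapping 150 kb windows); 483 k sample / 240 k reference reads
  (≈1500 reference reads per window, far above the 110-read design point
  and the 50-read mask); mtDNA rates 5% vs 1% (5×); telomere fractions
  0.5% vs 2% (0.25×) over 300 k FASTQ reads each. Recovery on this
  configuration: every CN ≤ 5 window rounds to the true integer, stratum
  means within 0.2 (CN ≤ 5) and within 2 at CN 25–29.
- `flat_config`: uniformly diploid single chromosome — the null scenario.
- `sex_mismatch_config`: XX sample against an XY reference — X called at
  CN 2, Y at CN 0.

## Numerical conventions

- Coordinates 0-based half-open internally; SAM and GFF converted on
  ingest, BED native; conversions are self-inverse.
- "Unique alignment" from SAM/BAM ≈ primary alignment with MAPQ ≥ 30
  (configurable); the tabular dialect carries pre-filtered reads and
  bypasses the question. The 5' coordinate is the leftmost aligned base
  regardless of strand — deterministic, and strand-symmetric at window
  scale. Duplicates are not removed (counting assumes they are real
  sampling events); pre-deduplicated input is equally valid.
- SEG output is log2(CN/ploidy) with CN floored at 0.01; masked rows are
  omitted from SEG (downstream viewers cannot represent them) but kept as
  `NA` in TSV, which round-trips losslessly.
- Histogram ties in mode estimation break toward the smaller ratio;
  `flag_variant_windows` uses a strict p < α (α = 1 returns everything);
  the optional Benjamini–Hochberg mode delegates to statsmodels.

## Known limitations

- No segmentation/breakpoint calling: output is per-window, not per-event.
- The modal-state-equals-ploidy assumption fails on predominantly
  non-diploid genomes (override via the ploidy map).
- Between-sample p-values are conservative when the shared reference is
  not much deeper than the samples (see above).
- Heterogeneous cell populations violate the homogeneity assumption behind
  the design calculation; fractional copy numbers are reported as-is.
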