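# Methods

## Coordinate and end conventions

All intervals are 0-based half-open (BED convention); BAM coordinates are
converted at the boundary by pysam. A mate pair becomes one fragment
spanning the outer extent of the two mates — the sequenced insert, which
in MNase ChIP is the protein-protected DNA. A motif's center is
`start + (width - 1) // 2` (for even widths, the left-of-center base);
every motif-relative offset in the package depends on this choice.
Fragment midpoints use floor division, again resolving even lengths
deterministically to the left.

A fragment's right end is reported at its half-open end coordinate, i.e.
the first unprotected base pair. This is the only convention under which
a fragment exactly spanning a 19-bp footprint yields end peaks separated
by 19 bp (left end at offset −9, right end at +10 around the center of a
19-bp motif), which is the quantity the end-profile and peak-pair
statistics are built to measure.

## Coverage and normalization

Raw coverage counts, at every base pair, the fragments whose interval
contains it (a difference-array accumulation, so a chromosome is
processed in O(fragments + length)). Normalized signal is the fraction
of mapped fragments spanning the position multiplied by the genome size:
`value' = value / n_total_mapped * genome_size`. `n_total_mapped` is
fixed at ingestion and deliberately preserved through size-class
filtering, so tracks from different size classes of one library share a
denominator and are directly comparable. The genome-wide mean of the
normalized track equals the mean fragment length of the set exactly —
an algebraic identity the test suite asserts to 1e-9 relative error.

Input normalization is a per-bp ratio of two normalized tracks with a
pseudocount (default 0.1) substituted where the control is zero. The
peak caller thresholds the normalized track: maximal runs at or above a
user-chosen threshold, runs separated by at most `max_gap` bp merged
(default 0), merged runs narrower than `min_width` bp dropped (default
10). No significance model is attached; the method targets data whose
background is low enough that plain thresholding suffices.

## Motif-centered aggregation

Signal matrices take the track values at offsets −flank..+flank around
each site center, reversing minus-strand rows so all rows share the
motif's reading direction; sites whose window would cross a chromosome
edge are dropped (padding would fabricate signal) and counted. End
profiles histogram fragment left/right ends per offset; on minus-strand
sites offsets are negated AND the left/right roles swap, so "left"
always means upstream of the motif. In single-end mode only the
informative read terminus is used: forward-read 5′ ends as left ends,
reverse-read 3′ ends as right ends — the read-end bias read-out for
sonicated data. V-plots count (site, fragment) incidences at (length,
midpoint offset); a fragment inside two sites' windows contributes to
both, which the ≥500 bp spacing filter makes rare on real site lists.
V-plot normalization offers `none` (default), `per_pixel` (divide by the
cell count) and `per_fragment` (divide by total incidences); the two
normalized variants are equivalent up to a constant and exist because
conventions differ between published displays.

## Resolution statistics

Half-height width: within ±flank (default 1000 bp) of a site, take the
maximum; estimate background as the median over the two outermost
`bg_margin` (default 100 bp) windows, lower-median convention for even
counts; threshold at max/2; report the length of the contiguous run of
offsets at or above threshold that contains the (leftmost) argmax.
Expressing the signal as a fold over a positive background before
halving selects the same offsets — dividing by a positive scalar
preserves the "≥ half of max" relation — so the background serves as QC
(`zero_background` flag) rather than entering the threshold. A
`midrise` mode (threshold = background + (max − background)/2) is
provided for sensitivity analysis. Anchoring the run to the argmax, not
the longest run anywhere, keeps the statistic about the peak at the
motif. Flat signals are flagged and excluded from summary quartiles.

Peak-pair separation: in split mode, argmax of left-end counts and
argmax of right-end counts; in combined mode, the two highest local
maxima of the summed counts at least `min_peak_distance` (default 5 bp)
apart, plateaus resolved to their leftmost offset. Separation is
reported only when the peaks straddle offset 0. The count of
"predominant" peaks uses a prominence fraction of the global maximum
(default 0.5).

The spacing filter keeps sites whose nearest same-chromosome neighbor,
measured center-to-center **against the original input set**, is at
least `min_sep` (default 500 bp) away; evaluating against the input
makes the filter idempotent and order-independent.

## Synthetic data generator

The generator produces the statistical structure the analysis assumes,
with per-fragment ground truth:

* **Footprint fragments**: per site, Poisson(`fragments_per_site`)
  fragments spanning the site plus independent per-side overhangs drawn
  geometric(`chew_p`) on support {0, 1, 2, ...}. The geometric is the
  simplest memoryless model whose mode is zero overhang — the nuclease
  most often chews exactly to the footprint edge. `chew_p` has no
  empirically calibrated value; 0.5 is the package default. Fragments
  that would cross a chromosome edge are discarded, never truncated.
* **Background**: placed uniformly at `background_rate` per kb; a
  `nucleosome_frac` (default 0.5) of them are nucleosome-sized
  (normal, mean 147 bp, sd 10) and the rest log-normal (median 250 bp,
  log-sd 0.4), standing in for crosslinked factor:nucleosome composites.
  No mechanistic crosslinking model is attempted — the analysis only
  consumes the length structure.
* **Sonication**: each of `n_sonicated_fragments` fragments gets one
  break position from a mixture (uniform over the genome with weight 1;
  Gaussian bumps, sd 50 bp, at anchor centers with total weight
  `accessibility_bias_weight`), a length uniform on
  [`sonication_len_min`, `sonication_len_max`] (defaults 200–500 bp),
  and the break as its left or right end with equal probability, the
  orientation also defining the originating-read strand. This is the
  simplest process with uniform lengths and accessibility-biased break
  positions; drawing fragments between consecutive breaks of a genome-
  wide point process would couple lengths to break density and violate
  the uniform-length property the tests assert.
* **Size selection**: independent retention with probability logistic in
  length, midpoint `selection_midpoint_len` (default 170 bp, the bead
  cutoff on ligated products) and slope `selection_steepness` (default
  0.05/bp; infinity gives a hard cutoff retaining lengths strictly below
  the midpoint). The report carries the below-50 bp fraction before and
  after and their ratio, the fold-enrichment statistic.

Randomness: one seed per simulate call; per-site sub-streams are spawned
from a `SeedSequence`, so output is reproducible and independent of site
iteration order. Limitations: no sequence content, mappability, PCR
duplicates or read errors are simulated, so passing tests demonstrate
the correctness of the downstream computation, not robustness to
alignment artifacts; duplicate fragments are retained throughout
(ingestion applies no deduplication).

## Problem sizes

The test suite and the benchmark script run entirely on synthetic data:
the largest instances are 500 sites × Poisson(200) fragments (~100k
fragments on a 5-Mb chromosome) for the end-peak benchmark and 50k
fragments (100k ends) on a 10-Mb chromosome for the sonication-bias
test; property tests use hundreds of random instances of span ≤ 201 bp
or ≤ 40 sites. These sizes give unambiguous statistics (the binomial
bias test at α = 0.01, exact oracle agreement elsewhere) in seconds to
a minute per test.

## Degenerate inputs and tie-breaks

Zero retained fragments at ingestion is an explicit error, as are empty
site lists and all-zero end profiles. Empty size-class results are legal
and propagate as empty sets. Argmax ties resolve to the leftmost offset
everywhere (half-height run anchor, end-profile peaks, local-maximum
plateaus). Even-count medians use the lower median. bedGraph output
merges adjacent equal values and omits zero runs; integer tracks
round-trip exactly, normalized tracks to better than 1e-9 relative
error (12 significant digits are written).
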