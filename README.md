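# hireschip

Fragment-length-aware analysis of high-resolution MNase X-ChIP-seq.

## The problem

Conventional ChIP-seq fragments chromatin by sonication, which yields
200–500 bp pieces — roughly ten times larger than the DNA footprint of a
typical transcription factor — and fragments chromatin non-randomly, with
accessible regions breaking more readily. Crosslinking ChIP with
micrococcal nuclease (MNase) instead digests all DNA not protected by
bound protein, so the sequenced paired-end insert *is* the protein's
footprint: for a factor bound to a 19-bp motif, fragment ends pile up at
the two edges of the motif and the shortest protected fragments are 19 bp
long. Extracting that information takes a specific downstream computation,
which this package implements for anyone producing or simulating
paired-end fragment data:

* **Ingestion** of fragments from BEDPE, fragment BED, or paired-end BAM
  (mate pairs collapsed to the insert span), and of motif/anchor sites
  from BED6.
* **Size-class stratification** (e.g. 20–50 bp sub-nucleosomal fragments
  vs ~147 bp nucleosomal ones) with exact length histograms.
* **Coverage** per base pair, normalized as the fraction of mapped
  fragments spanning each position multiplied by the genome size, written
  as bedGraph; plus a simple thresholding peak caller.
* **Motif-centered aggregation**: per-site signal matrices and average
  profiles, fragment-end profiles (left/right end counts per offset), and
  V-plots (fragment midpoint offset vs length).
* **Resolution statistics**: per-site half-height peak width, end-peak
  pair separation, and the ≥500 bp motif spacing filter.
* **A synthetic fragment generator** with full ground truth — footprint
  fragments with geometric MNase chew-back, nucleosomal/composite
  background, accessibility-biased sonication, and logistic bead-based
  size selection — so every stage of the pipeline is testable at desk
  scale.

## Core statistics

For a site with signal $s(x)$ at motif-relative offsets
$x \in [-f, +f]$, the **half-height width** is the number of contiguous
base pairs, in the run containing the signal maximum, with
$s(x) \ge \max(s)/2$; the local background (median of $s$ over
$[-f, -f{+}100]$ and $[f{-}100, f]$) is reported for QC. Sharper peaks
give smaller widths.

The **end-peak separation** is $\text{argmax}$ of right-end counts minus
$\text{argmax}$ of left-end counts, with the right end reported at the
half-open end coordinate (first unprotected bp), so a fragment exactly
spanning a 19-bp footprint contributes ends separated by 19 bp.

The **V-plot** counts (site, fragment) incidences at (fragment length,
midpoint offset); its apex — the minimum occupied length at offset 0 —
estimates the minimal protected footprint.

## Worked example

```python
import hireschip as h

genome = h.GenomeInfo({"chr1": 1_000_000})
sites = [h.MotifSite("chr1", s, s + 19, name=f"ctcf_{i}")
         for i, s in enumerate(range(5_000, 995_000, 5_000))]

# simulate a factor ChIP: 19-bp footprints, geometric(0.5) chew-back,
# light nucleosomal/composite background
cfg = h.SynthConfig(seed=42, fragments_per_site=100, chew_p=0.5,
                    background_rate=0.5)
fs, truth = h.simulate_tf_chip(genome, sites, cfg)
print(len(fs))                                  # 20225

dist = h.length_distribution(fs)
print(dist.fraction_in(20, 70), dist.fraction_below(50))  # 0.731 0.975

sub = h.filter_by_size(fs, h.SizeClass(20, 50))
track = h.normalize_coverage(h.compute_coverage(sub, genome),
                             sub.n_total_mapped, genome.genome_size)
kept = h.motif_spacing_filter(sites, 500)
pm = h.site_matrix(track, kept, flank=1000)
_, summary = h.half_height_widths(pm, bg_margin=100)
print(summary)   # {'n': 198, 'q1': 21.0, 'median': 21.0, 'q3': 21.0}

ep = h.end_profile(fs, kept, flank=100)
pair = h.peak_pair_separation(ep, source="split")
print(pair.left_peak_offset, pair.right_peak_offset, pair.separation)
# -9 10 19  -> end peaks at the footprint edges, separated by 19 bp

vm = h.vplot(fs, kept, flank=60, len_min=1, len_max=200)
print(vm.apex_length())                         # 19
```

The median half-height width of 21 bp says the 20–50 bp fragment class
resolves the 19-bp footprint to near base-pair precision; the end-peak
separation of 19 bp and the V-plot apex at length 19 both recover the
configured footprint exactly.

Size selection enriches a nucleosome-dominated input for short inserts
(the bead cutoff acts on the adapter-ligated product, ~125 bp longer than
the insert, so the effective insert midpoint is well below 170 bp):

```python
icfg = h.SynthConfig(seed=7, fragments_per_site=2, background_rate=20.0,
                     nucleosome_frac=0.9,
                     selection_midpoint_len=75.0, selection_steepness=0.1)
inp, _ = h.simulate_tf_chip(genome, sites, icfg)
sel, rep = h.apply_size_selection(inp, icfg)
print(f"{rep.fraction_below_before:.4f} -> {rep.fraction_below_after:.4f} "
      f"({rep.fold_enrichment:.1f}-fold)")
# 0.0201 -> 0.9197 (45.8-fold)
```

## Command line

Every stage is also a `hireschip` subcommand (`simulate`, `coverage`,
`profile`, `ends`, `vplot`, `metrics`, `peaks`), and `hireschip run
--config run.yaml` executes the full simulate → coverage → profiles →
metrics pipeline reproducibly: identical config and seed give
byte-identical outputs.

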