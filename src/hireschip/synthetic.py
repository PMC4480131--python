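"""Synthetic paired-end fragment generator with ground truth.

The generator emulates the statistical structure the analysis assumes:

* **Footprint fragments** protected by a bound factor: each fragment spans
  the motif footprint plus independent per-side overhangs drawn from a
  geometric distribution with support {0, 1, 2, ...} and mode 0 — the
  nuclease chews back to the footprint edge most often, sometimes leaving
  a few unprotected bp.
* **Nucleosomal and composite background**: nucleosome-sized fragments
  (normal, ~147 bp) and longer log-normal fragments standing in for
  crosslinked factor:nucleosome composites, placed uniformly.
* **Sonicated fragments** (separate simulator): 200-500 bp fragments whose
  break positions mix a uniform genomic component with Gaussian bumps at
  accessible anchors, emulating non-random chromatin fragmentation.
* **Size selection**: length-dependent retention with a logistic profile
  centered at the bead cutoff, emulating enrichment of short inserts.

Sequence content is not simulated; the pipeline consumes intervals only.
All randomness flows from a single seed; per-site sub-streams are derived
deterministically so output is fully reproducible.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from hireschip.io_formats import FragmentSet, GenomeInfo, MotifSite


@dataclass
class SynthConfig:
    """Generator parameters. Defaults are the study conditions emulated:
    a 19-bp factor footprint, geometric(0.5) chew-back, ~147 bp
    nucleosomes, 200-500 bp sonication, and a ~170 bp selection cutoff."""

    footprint_len: int = 19
    chew_p: float = 0.5                 # geometric success prob; support 0,1,2,...
    fragments_per_site: float = 200.0   # Poisson mean per site
    nucleosome_len_mean: float = 147.0
    nucleosome_len_sd: float = 10.0
    nucleosome_frac: float = 0.5        # fraction of background that is nucleosomal
    background_rate: float = 0.0        # fragments per kb of genome
    background_len_logmean: float = math.log(250.0)
    background_len_logsd: float = 0.4
    sonication_len_min: int = 200
    sonication_len_max: int = 500
    accessibility_bias_weight: float = 0.0
    accessibility_sd: float = 50.0      # bp, width of the anchor bumps
    n_sonicated_fragments: int = 50_000
    selection_midpoint_len: float = 170.0
    selection_steepness: float = 0.05   # per bp; math.inf = hard cutoff
    seed: int = 0

    def __post_init__(self) -> None:
        if self.footprint_len < 1:
            raise ValueError("footprint_len must be >= 1")
        if not (0.0 < self.chew_p <= 1.0):
            raise ValueError("chew_p must be in (0, 1]")
        if self.sonication_len_min > self.sonication_len_max:
            raise ValueError("sonication length bounds out of order")
        if self.accessibility_bias_weight < 0:
            raise ValueError("accessibility_bias_weight must be >= 0")


@dataclass(frozen=True)
class TruthRecord:
    """Ground-truth origin of one emitted fragment."""

    origin: str                  # footprint | nucleosome | background | sonicated
    site_id: str | None = None
    overhang_left: int | None = None
    overhang_right: int | None = None


@dataclass
class SizeSelectionReport:
    """Before/after short-fragment fractions and their fold enrichment."""

    threshold: int
    n_before: int
    n_after: int
    fraction_below_before: float
    fraction_below_after: float

    @property
    def fold_enrichment(self) -> float:
        if self.fraction_below_before == 0:
            return float("inf") if self.fraction_below_after > 0 else float("nan")
        return self.fraction_below_after / self.fraction_below_before


def _geometric0(rng: np.random.Generator, p: float, size: int) -> np.ndarray:
    """Geometric draws with support {0, 1, 2, ...} and mode 0."""
    if p >= 1.0:
        return np.zeros(size, dtype=np.int64)
    return rng.geometric(p, size=size) - 1


def _sorted_with_truth(
    chroms: list, starts: list, ends: list, truth: list[TruthRecord],
    provenance: list[str],
) -> tuple[FragmentSet, list[TruthRecord]]:
    df = pd.DataFrame(
        {"chrom": chroms, "start": np.asarray(starts, dtype=np.int64),
         "end": np.asarray(ends, dtype=np.int64)}
    )
    order = df.sort_values(["chrom", "start", "end"], kind="mergesort").index.to_numpy()
    df = df.iloc[order].reset_index(drop=True)
    truth_sorted = [truth[i] for i in order]
    fs = FragmentSet(df, n_total_mapped=len(df), provenance=provenance, sort=False)
    return fs, truth_sorted


def simulate_tf_chip(
    genome: GenomeInfo,
    sites: Sequence[MotifSite],
    config: SynthConfig,
) -> tuple[FragmentSet, list[TruthRecord]]:
    """Simulate factor-footprint ChIP fragments around motif sites.

    Per site, Poisson(fragments_per_site) fragments are emitted spanning
    [site.start - L_ov, site.end + R_ov) with independent geometric(chew_p)
    overhangs. Background fragments (nucleosomal plus log-normal composite)
    are placed uniformly at ``background_rate`` per kb. Fragments that
    would extend past a chromosome edge are discarded, not truncated.
    """
    for s in sites:
        if s.chrom not in genome or s.end > genome.length_of(s.chrom):
            raise ValueError(f"site {s.chrom}:[{s.start},{s.end}) outside genome")

    ss = np.random.SeedSequence(config.seed)
    site_streams = ss.spawn(len(sites) + 1)
    chroms: list[str] = []
    starts: list[int] = []
    ends: list[int] = []
    truth: list[TruthRecord] = []
    n_edge_discarded = 0

    for idx, site in enumerate(sites):
        rng = np.random.default_rng(site_streams[idx])
        n = int(rng.poisson(config.fragments_per_site))
        if n == 0:
            continue
        lov = _geometric0(rng, config.chew_p, n)
        rov = _geometric0(rng, config.chew_p, n)
        fs = site.start - lov
        fe = site.end + rov
        clen = genome.length_of(site.chrom)
        ok = (fs >= 0) & (fe <= clen)
        n_edge_discarded += int(np.count_nonzero(~ok))
        sid = site.name if site.name != "." else f"{site.chrom}:{site.start}-{site.end}"
        for a, b, lo, ro in zip(fs[ok], fe[ok], lov[ok], rov[ok]):
            chroms.append(site.chrom)
            starts.append(int(a))
            ends.append(int(b))
            truth.append(TruthRecord("footprint", sid, int(lo), int(ro)))

    # background: nucleosomal + composite log-normal, uniform placement
    if config.background_rate > 0:
        rng = np.random.default_rng(site_streams[-1])
        chrom_names = list(genome.chrom_lengths)
        chrom_lens = np.array([genome.length_of(c) for c in chrom_names], dtype=np.float64)
        n_bg = int(rng.poisson(config.background_rate * genome.genome_size / 1000.0))
        if n_bg:
            which = rng.choice(len(chrom_names), size=n_bg, p=chrom_lens / chrom_lens.sum())
            is_nuc = rng.random(n_bg) < config.nucleosome_frac
            lens = np.where(
                is_nuc,
                np.maximum(
                    1,
                    np.rint(rng.normal(config.nucleosome_len_mean,
                                       config.nucleosome_len_sd, n_bg)),
                ),
                np.maximum(1, np.rint(rng.lognormal(config.background_len_logmean,
                                                    config.background_len_logsd, n_bg))),
            ).astype(np.int64)
            u = rng.random(n_bg)
            for k in range(n_bg):
                clen = int(chrom_lens[which[k]])
                L = int(lens[k])
                if L >= clen:
                    n_edge_discarded += 1
                    continue
                s0 = int(u[k] * (clen - L))
                chroms.append(chrom_names[which[k]])
                starts.append(s0)
                ends.append(s0 + L)
                truth.append(
                    TruthRecord("nucleosome" if is_nuc[k] else "background")
                )

    prov = [
        f"simulate_tf_chip seed={config.seed} sites={len(sites)} "
        f"chew_p={config.chew_p} edge_discarded={n_edge_discarded}"
    ]
    return _sorted_with_truth(chroms, starts, ends, truth, prov)


def simulate_sonicated_chip(
    genome: GenomeInfo,
    anchors: Sequence[MotifSite],
    config: SynthConfig,
) -> tuple[FragmentSet, list[TruthRecord]]:
    """Simulate sonication-fragmented ChIP with accessibility-biased breaks.

    Each fragment gets one break position drawn from a mixture — uniform
    over the genome with weight 1, plus Gaussian bumps (sd
    ``accessibility_sd``) at anchor centers with total weight
    ``accessibility_bias_weight`` — a length uniform on
    [sonication_len_min, sonication_len_max], and the break as its left or
    right end with equal probability. Fragments extending past a
    chromosome edge are discarded.
    """
    rng = np.random.default_rng(np.random.SeedSequence(config.seed).spawn(1)[0])
    chrom_names = list(genome.chrom_lengths)
    chrom_lens = np.array([genome.length_of(c) for c in chrom_names], dtype=np.float64)
    cum = np.concatenate(([0.0], np.cumsum(chrom_lens)))
    w = config.accessibility_bias_weight
    p_bump = w / (1.0 + w) if (w > 0 and anchors) else 0.0

    n = config.n_sonicated_fragments
    chroms: list[str] = []
    starts: list[int] = []
    ends: list[int] = []
    strands: list[str] = []
    truth: list[TruthRecord] = []

    use_bump = rng.random(n) < p_bump
    lens = rng.integers(config.sonication_len_min, config.sonication_len_max + 1, size=n)
    break_is_left = rng.random(n) < 0.5
    anchor_idx = rng.integers(0, max(len(anchors), 1), size=n)
    bump_offsets = rng.normal(0.0, config.accessibility_sd, size=n)
    flat_pos = rng.random(n) * genome.genome_size

    for k in range(n):
        if use_bump[k]:
            a = anchors[int(anchor_idx[k])]
            chrom = a.chrom
            b = int(round(a.center + bump_offsets[k]))
        else:
            g = float(flat_pos[k])
            ci = int(np.searchsorted(cum, g, side="right") - 1)
            ci = min(ci, len(chrom_names) - 1)
            chrom = chrom_names[ci]
            b = int(g - cum[ci])
        L = int(lens[k])
        if break_is_left[k]:
            s0, e0, strand = b, b + L, "+"
        else:
            s0, e0, strand = b - L, b, "-"
        clen = genome.length_of(chrom)
        if s0 < 0 or e0 > clen:
            continue
        chroms.append(chrom)
        starts.append(s0)
        ends.append(e0)
        strands.append(strand)
        truth.append(TruthRecord("sonicated"))

    df = pd.DataFrame(
        {"chrom": chroms, "start": np.asarray(starts, dtype=np.int64),
         "end": np.asarray(ends, dtype=np.int64), "strand": strands}
    )
    order = df.sort_values(["chrom", "start", "end"], kind="mergesort").index.to_numpy()
    df = df.iloc[order].reset_index(drop=True)
    truth_sorted = [truth[i] for i in order]
    fs = FragmentSet(
        df[["chrom", "start", "end"]],
        n_total_mapped=len(df),
        provenance=[
            f"simulate_sonicated_chip seed={config.seed} n={n} bias_weight={w}"
        ],
        sort=False,
    )
    fs.df["strand"] = df["strand"]
    return fs, truth_sorted


def retention_probability(length: np.ndarray | float, config: SynthConfig) -> np.ndarray:
    """Logistic length-dependent retention of bead-based size selection."""
    L = np.asarray(length, dtype=np.float64)
    if math.isinf(config.selection_steepness):
        return (L < config.selection_midpoint_len).astype(np.float64)
    from scipy.special import expit

    z = config.selection_steepness * (L - config.selection_midpoint_len)
    return expit(-z)


def apply_size_selection(
    fragset: FragmentSet,
    config: SynthConfig,
    threshold: int = 50,
) -> tuple[FragmentSet, SizeSelectionReport]:
    """Retain each fragment independently with logistic probability in
    length, and report the fold enrichment of the sub-threshold fraction.
    """
    rng = np.random.default_rng(np.random.SeedSequence(config.seed).spawn(2)[1])
    lengths = fragset.lengths
    p = retention_probability(lengths, config)
    keep = rng.random(len(lengths)) < p
    sub = fragset.df[keep].reset_index(drop=True)
    out = fragset.with_fragments(
        sub, f"apply_size_selection midpoint={config.selection_midpoint_len} "
             f"steepness={config.selection_steepness}: {len(sub)}/{len(lengths)} kept"
    )
    n_before = len(lengths)
    n_after = int(keep.sum())
    frac_before = float(np.count_nonzero(lengths < threshold)) / n_before if n_before else 0.0
    frac_after = (
        float(np.count_nonzero(lengths[keep] < threshold)) / n_after if n_after else 0.0
    )
    report = SizeSelectionReport(
        threshold=threshold,
        n_before=n_before,
        n_after=n_after,
        fraction_below_before=frac_before,
        fraction_below_after=frac_after,
    )
    return out, report


def truth_to_tsv(truth: Sequence[TruthRecord], path) -> None:
    with open(path, "w") as fh:
        fh.write("origin\tsite_id\toverhang_left\toverhang_right\n")
        for t in truth:
            fh.write(
                f"{t.origin}\t{t.site_id or '.'}\t"
                f"{'.' if t.overhang_left is None else t.overhang_left}\t"
                f"{'.' if t.overhang_right is None else t.overhang_right}\n"
            )
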