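"""Per-base fragment coverage, normalization, and thresholding peak calls.

Normalized signal follows the fraction-of-reads convention: the fraction of
mapped fragments spanning each base pair, multiplied by the genome size.
The genome-wide mean of this quantity equals the mean fragment length of
the set, which serves as an exact numerical check.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np

from hireschip.io_formats import FragmentSet, GenomeInfo


@dataclass
class CoverageTrack:
    """Per-chromosome per-bp values, raw fragment counts or normalized."""

    values: Mapping[str, np.ndarray]
    genome: GenomeInfo
    scale: str = "raw_counts"  # raw_counts | normalized | ratio
    n_total_mapped: int | None = None
    genome_size: int | None = None

    def __post_init__(self) -> None:
        if set(self.values) != set(self.genome.chrom_lengths):
            raise ValueError("track chromosomes do not match its genome")
        for chrom, arr in self.values.items():
            if len(arr) != self.genome.length_of(chrom):
                raise ValueError(f"track length mismatch on {chrom}")

    def total(self) -> float:
        return float(sum(arr.sum() for arr in self.values.values()))

    def mean(self) -> float:
        return self.total() / self.genome.genome_size

    def max(self) -> float:
        return float(max(arr.max() if len(arr) else 0 for arr in self.values.values()))

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, CoverageTrack):
            return NotImplemented
        return set(self.values) == set(other.values) and all(
            np.array_equal(self.values[c], other.values[c]) for c in self.values
        )


@dataclass(frozen=True)
class PeakInterval:
    """A called peak: a maximal above-threshold run, 0-based half-open."""

    chrom: str
    start: int
    end: int
    max_value: float
    mean_value: float


def compute_coverage(fragset: FragmentSet, genome: GenomeInfo) -> CoverageTrack:
    """Count, at every bp, the fragments whose interval contains it."""
    values: dict[str, np.ndarray] = {}
    for chrom, length in genome.chrom_lengths.items():
        starts, ends = fragset.for_chrom(chrom)
        if len(starts) and (starts.min() < 0 or ends.max() > length):
            i = int(np.argmax((starts < 0) | (ends > length)))
            bad = np.flatnonzero((starts < 0) | (ends > length))[0]
            raise ValueError(
                f"fragment {chrom}:[{starts[bad]},{ends[bad]}) outside genome "
                f"(length {length})"
            )
        diff = np.zeros(length + 1, dtype=np.int64)
        np.add.at(diff, starts, 1)
        np.add.at(diff, ends, -1)
        values[chrom] = np.cumsum(diff[:-1])
    unknown = set(fragset.df["chrom"].unique()) - set(genome.chrom_lengths)
    if unknown:
        raise ValueError(f"fragments on chromosomes not in genome: {sorted(unknown)}")
    return CoverageTrack(values=values, genome=genome, scale="raw_counts")


def normalize_coverage(
    track: CoverageTrack, n_total_mapped: int, genome_size: int | None = None
) -> CoverageTrack:
    """Scale raw counts to (count / n_total_mapped) * genome_size per bp."""
    if track.scale != "raw_counts":
        raise ValueError("normalize_coverage requires a raw_counts track")
    if n_total_mapped <= 0:
        raise ValueError("n_total_mapped must be positive")
    gsize = track.genome.genome_size if genome_size is None else int(genome_size)
    if gsize <= 0:
        raise ValueError("genome_size must be positive")
    factor = gsize / n_total_mapped
    values = {c: arr.astype(np.float64) * factor for c, arr in track.values.items()}
    return CoverageTrack(
        values=values,
        genome=track.genome,
        scale="normalized",
        n_total_mapped=n_total_mapped,
        genome_size=gsize,
    )


def input_normalize(
    chip: CoverageTrack, control: CoverageTrack, pseudocount: float = 0.1
) -> CoverageTrack:
    """Per-bp ratio of two normalized tracks, with a pseudocount in the
    denominator wherever the control is zero."""
    if chip.scale != "normalized" or control.scale != "normalized":
        raise ValueError("input_normalize requires two normalized tracks")
    if set(chip.values) != set(control.values):
        raise ValueError("tracks are over different genomes")
    values = {}
    for chrom in chip.values:
        denom = control.values[chrom].copy()
        denom[denom == 0] = pseudocount
        values[chrom] = chip.values[chrom] / denom
    return CoverageTrack(values=values, genome=chip.genome, scale="ratio")


def threshold_peaks(
    track: CoverageTrack,
    threshold: float,
    min_width: int = 10,
    max_gap: int = 0,
) -> list[PeakInterval]:
    """Call peaks as maximal runs of bp with value >= threshold.

    Runs separated by at most ``max_gap`` bp of sub-threshold signal are
    merged; merged runs narrower than ``min_width`` are discarded. Output
    is sorted by (chrom, start).
    """
    if threshold <= 0:
        raise ValueError("threshold must be positive")
    peaks: list[PeakInterval] = []
    for chrom in sorted(track.values):
        vals = track.values[chrom]
        above = vals >= threshold
        if not above.any():
            continue
        edges = np.diff(above.astype(np.int8))
        starts = np.flatnonzero(edges == 1) + 1
        ends = np.flatnonzero(edges == -1) + 1
        if above[0]:
            starts = np.concatenate(([0], starts))
        if above[-1]:
            ends = np.concatenate((ends, [len(vals)]))
        # merge runs whose gap is <= max_gap
        merged: list[list[int]] = []
        for s, e in zip(starts, ends):
            if merged and s - merged[-1][1] <= max_gap:
                merged[-1][1] = e
            else:
                merged.append([int(s), int(e)])
        for s, e in merged:
            if e - s < min_width:
                continue
            seg = vals[s:e]
            peaks.append(
                PeakInterval(chrom, s, e, float(seg.max()), float(seg.mean()))
            )
    return peaks


def peaks_to_bed(peaks: list[PeakInterval], path) -> None:
    """Write peaks as BED6; score = max_value scaled to 0-1000 over the set."""
    top = max((p.max_value for p in peaks), default=1.0) or 1.0
    with open(path, "w") as fh:
        for i, p in enumerate(peaks):
            score = int(round(1000 * p.max_value / top))
            fh.write(f"{p.chrom}\t{p.start}\t{p.end}\tpeak_{i}\t{score}\t.\n")
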