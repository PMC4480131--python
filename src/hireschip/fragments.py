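"""Size-class stratification and fragment-length statistics.

Paired-end fragments are divided into length classes (e.g. 20-50 bp for
factor-sized footprints, ~147 bp for nucleosomal protection). Class bounds
are inclusive on both ends: "20-70 bp" retains lengths 20 and 70.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from hireschip.io_formats import Fragment, FragmentSet


@dataclass(frozen=True)
class SizeClass:
    """An inclusive fragment-length range in bp."""

    min_len: int
    max_len: int

    def __post_init__(self) -> None:
        if not (1 <= self.min_len <= self.max_len):
            raise ValueError(f"invalid size class {self.min_len}-{self.max_len}")

    @property
    def label(self) -> str:
        return f"{self.min_len}-{self.max_len}"

    @classmethod
    def parse(cls, text: str) -> "SizeClass":
        """Parse 'MIN:MAX' or 'MIN-MAX' notation."""
        sep = ":" if ":" in text else "-"
        lo, hi = text.split(sep)
        return cls(int(lo), int(hi))


class LengthDistribution:
    """Exact integer histogram of fragment lengths."""

    def __init__(self, lengths: np.ndarray) -> None:
        lengths = np.asarray(lengths, dtype=np.int64)
        if lengths.size == 0:
            raise ValueError("cannot build a length distribution from zero fragments")
        vals, counts = np.unique(lengths, return_counts=True)
        self.counts: dict[int, int] = dict(zip(vals.tolist(), counts.tolist()))
        self.total = int(lengths.size)
        self._lengths = lengths

    def fraction_in(self, min_len: int, max_len: int) -> float:
        """Fraction of fragments with min_len <= length <= max_len."""
        n = int(np.count_nonzero((self._lengths >= min_len) & (self._lengths <= max_len)))
        return n / self.total

    def fraction_below(self, threshold: int, strict: bool = True) -> float:
        """Fraction of fragments with length < threshold (<= if strict=False)."""
        if strict:
            n = int(np.count_nonzero(self._lengths < threshold))
        else:
            n = int(np.count_nonzero(self._lengths <= threshold))
        return n / self.total

    def to_tsv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write("length\tcount\n")
            for length in sorted(self.counts):
                fh.write(f"{length}\t{self.counts[length]}\n")


def filter_by_size(fragset: FragmentSet, size_class: SizeClass) -> FragmentSet:
    """Retain fragments whose length falls in the class (inclusive bounds).

    ``n_total_mapped`` is preserved from the parent set so that coverage
    normalization keeps its ingestion-time denominator.
    """
    lengths = fragset.df["end"] - fragset.df["start"]
    mask = (lengths >= size_class.min_len) & (lengths <= size_class.max_len)
    sub = fragset.df[mask].reset_index(drop=True)
    return fragset.with_fragments(sub, f"filter_by_size {size_class.label}: {len(sub)} kept")


def length_distribution(fragset: FragmentSet) -> LengthDistribution:
    """The integer histogram of fragment lengths in the set."""
    return LengthDistribution(fragset.lengths)


def fragment_midpoint(f: Fragment) -> int:
    """Midpoint coordinate, floor((start + end) / 2), 0-based."""
    return (f.start + f.end) // 2


def midpoints(fragset: FragmentSet) -> np.ndarray:
    """Vectorized midpoints for every fragment in set order."""
    return ((fragset.df["start"] + fragset.df["end"]) // 2).to_numpy()
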