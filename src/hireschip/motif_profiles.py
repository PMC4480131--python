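"""Motif-centered aggregation: signal matrices, end profiles, V-plots.

Everything is expressed in motif-relative offsets, -flank..+flank bp around
each site's center, with minus-strand sites orientation-flipped so that all
rows share the motif's reading direction.

End-coordinate convention: a fragment's left end is reported at its start
coordinate and its right end at its half-open end coordinate (the first
unprotected bp). A fragment exactly spanning a 19-bp footprint therefore
yields left/right end peaks separated by 19 bp, matching the width of the
protected motif.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from hireschip.io_formats import FragmentSet, MotifSite
from hireschip.coverage import CoverageTrack


@dataclass
class ProfileMatrix:
    """Per-site signal rows over motif-relative offsets."""

    matrix: np.ndarray          # (n_sites, 2*flank+1)
    offsets: np.ndarray         # -flank..+flank
    site_ids: list[str]
    n_dropped: int = 0

    @property
    def flank(self) -> int:
        return int((len(self.offsets) - 1) // 2)

    def to_tsv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write("site_id\t" + "\t".join(str(o) for o in self.offsets) + "\n")
            for sid, row in zip(self.site_ids, self.matrix):
                fh.write(sid + "\t" + "\t".join(f"{v:.12g}" for v in row) + "\n")


@dataclass
class EndProfile:
    """Fragment-end counts per motif-relative offset.

    ``left_counts[i]`` counts fragment left ends at ``offsets[i]``; same
    for right ends. ``combined`` is their sum.
    """

    offsets: np.ndarray
    left_counts: np.ndarray
    right_counts: np.ndarray
    mode: str = "paired_end"

    @property
    def combined(self) -> np.ndarray:
        return self.left_counts + self.right_counts

    def to_tsv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write("offset\tleft\tright\tcombined\n")
            for o, l, r in zip(self.offsets, self.left_counts, self.right_counts):
                fh.write(f"{o}\t{l}\t{r}\t{l + r}\n")


@dataclass
class VPlotMatrix:
    """Counts of fragment (length, midpoint-offset) incidences.

    The apex — the minimum occupied length at offset 0 — marks the minimal
    protected footprint.
    """

    matrix: np.ndarray          # (n_lengths, 2*flank+1)
    lengths: np.ndarray         # len_min..len_max
    offsets: np.ndarray         # -flank..+flank
    normalization_mode: str = "none"

    def apex_length(self) -> int | None:
        """Smallest length with non-zero mass at offset 0, or None."""
        col = self.matrix[:, len(self.offsets) // 2]
        occupied = np.flatnonzero(col > 0)
        return int(self.lengths[occupied[0]]) if occupied.size else None

    def column_sums(self) -> np.ndarray:
        return self.matrix.sum(axis=0)

    def to_tsv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write("length\t" + "\t".join(str(o) for o in self.offsets) + "\n")
            for L, row in zip(self.lengths, self.matrix):
                fh.write(str(L) + "\t" + "\t".join(f"{v:.12g}" for v in row) + "\n")


def _site_id(site: MotifSite, index: int) -> str:
    if site.name and site.name != ".":
        return site.name
    return f"{site.chrom}:{site.start}-{site.end}({site.strand})"


def site_matrix(
    track: CoverageTrack, sites: Sequence[MotifSite], flank: int
) -> ProfileMatrix:
    """Extract per-site signal rows +-flank bp around each site center.

    Minus-strand rows are reversed before storage. Sites whose window
    exceeds chromosome bounds are dropped and counted in ``n_dropped``.
    """
    if flank < 1:
        raise ValueError("flank must be >= 1")
    if not sites:
        raise ValueError("empty site list")
    rows, ids = [], []
    dropped = 0
    for i, site in enumerate(sites):
        if site.chrom not in track.values:
            dropped += 1
            continue
        vals = track.values[site.chrom]
        c = site.center
        if c - flank < 0 or c + flank + 1 > len(vals):
            dropped += 1
            continue
        row = vals[c - flank : c + flank + 1].astype(np.float64)
        if site.strand == "-":
            row = row[::-1]
        rows.append(row)
        ids.append(_site_id(site, i))
    matrix = np.vstack(rows) if rows else np.empty((0, 2 * flank + 1))
    return ProfileMatrix(
        matrix=matrix,
        offsets=np.arange(-flank, flank + 1),
        site_ids=ids,
        n_dropped=dropped,
    )


def average_profile(matrix: ProfileMatrix) -> np.ndarray:
    """Per-offset arithmetic mean across sites."""
    if matrix.matrix.shape[0] == 0:
        raise ValueError("cannot average a profile matrix with zero rows")
    return matrix.matrix.mean(axis=0)


def _accumulate_ends(
    counts: np.ndarray, positions: np.ndarray, center: int, flank: int, flip: bool
) -> None:
    """Add end positions (sorted) near one site into an offset histogram."""
    lo, hi = center - flank, center + flank
    i0 = np.searchsorted(positions, lo, side="left")
    i1 = np.searchsorted(positions, hi, side="right")
    if i1 <= i0:
        return
    offs = positions[i0:i1] - center
    if flip:
        offs = -offs
    np.add.at(counts, offs + flank, 1)


def end_profile(
    fragset: FragmentSet,
    sites: Sequence[MotifSite],
    flank: int,
    mode: str = "paired_end",
) -> EndProfile:
    """Count fragment ends per motif-relative offset across all sites.

    paired_end mode: every fragment contributes its left end at offset
    (start - center) and its right end at (end - center), when within
    +-flank. Minus-strand sites negate offsets AND swap the left/right
    roles, so "left" always means upstream in the motif's orientation.

    single_end_bias mode emulates single-end sonication data: only the
    sequenced read's 5' terminus is informative, so forward-strand reads
    contribute their start as a left end and reverse-strand reads their
    (half-open) end as a right end. Requires a "strand" column on the
    fragment table.
    """
    if mode not in ("paired_end", "single_end_bias"):
        raise ValueError(f"unknown end_profile mode {mode!r}")
    n = 2 * flank + 1
    left = np.zeros(n, dtype=np.int64)
    right = np.zeros(n, dtype=np.int64)

    if mode == "single_end_bias" and "strand" not in fragset.df.columns:
        raise ValueError("single_end_bias mode requires fragment strands")

    by_chrom: dict[str, tuple[np.ndarray, np.ndarray]] = {}
    for chrom in fragset.df["chrom"].unique():
        sub = fragset.df[fragset.df["chrom"] == chrom]
        if mode == "paired_end":
            starts = np.sort(sub["start"].to_numpy())
            ends = np.sort(sub["end"].to_numpy())
        else:
            fwd = sub[sub["strand"] == "+"]
            rev = sub[sub["strand"] == "-"]
            starts = np.sort(fwd["start"].to_numpy())
            ends = np.sort(rev["end"].to_numpy())
        by_chrom[chrom] = (starts, ends)

    for site in sites:
        if site.chrom not in by_chrom:
            continue
        starts, ends = by_chrom[site.chrom]
        c = site.center
        if site.strand == "+":
            _accumulate_ends(left, starts, c, flank, flip=False)
            _accumulate_ends(right, ends, c, flank, flip=False)
        else:
            # flipped orientation: genomic right ends become motif-left ends
            _accumulate_ends(left, ends, c, flank, flip=True)
            _accumulate_ends(right, starts, c, flank, flip=True)

    return EndProfile(
        offsets=np.arange(-flank, flank + 1),
        left_counts=left,
        right_counts=right,
        mode=mode,
    )


def vplot(
    fragset: FragmentSet,
    sites: Sequence[MotifSite],
    flank: int,
    len_min: int,
    len_max: int,
    normalization_mode: str = "none",
) -> VPlotMatrix:
    """Fragment midpoint-offset vs length incidence map around sites.

    One count at (length L, offset m) per (site, fragment) pair with
    fragment length L in [len_min, len_max] and strand-flipped midpoint
    offset m in [-flank, +flank]. A fragment near two sites contributes
    to both. Normalization: "none" leaves counts; "per_pixel" divides by
    the number of matrix cells; "per_fragment" divides by the total
    incidence count.
    """
    if len_min > len_max:
        raise ValueError("len_min must be <= len_max")
    if flank < 1:
        raise ValueError("flank must be >= 1")
    if normalization_mode not in ("none", "per_pixel", "per_fragment"):
        raise ValueError(f"unknown normalization mode {normalization_mode!r}")

    lengths = np.arange(len_min, len_max + 1)
    offsets = np.arange(-flank, flank + 1)
    matrix = np.zeros((len(lengths), len(offsets)), dtype=np.float64)

    by_chrom: dict[str, tuple[np.ndarray, np.ndarray]] = {}
    for chrom in fragset.df["chrom"].unique():
        sub = fragset.df[fragset.df["chrom"] == chrom]
        mids = ((sub["start"] + sub["end"]) // 2).to_numpy()
        lens = (sub["end"] - sub["start"]).to_numpy()
        order = np.argsort(mids, kind="mergesort")
        by_chrom[chrom] = (mids[order], lens[order])

    for site in sites:
        if site.chrom not in by_chrom:
            continue
        mids, lens = by_chrom[site.chrom]
        c = site.center
        i0 = np.searchsorted(mids, c - flank, side="left")
        i1 = np.searchsorted(mids, c + flank, side="right")
        if i1 <= i0:
            continue
        m = mids[i0:i1] - c
        if site.strand == "-":
            m = -m
        L = lens[i0:i1]
        keep = (L >= len_min) & (L <= len_max)
        np.add.at(matrix, (L[keep] - len_min, m[keep] + flank), 1.0)

    if normalization_mode == "per_pixel":
        matrix = matrix / matrix.size
    elif normalization_mode == "per_fragment":
        total = matrix.sum()
        if total > 0:
            matrix = matrix / total

    return VPlotMatrix(
        matrix=matrix,
        lengths=lengths,
        offsets=offsets,
        normalization_mode=normalization_mode,
    )


def render_heatmap(matrix: ProfileMatrix | VPlotMatrix, path) -> None:
    """Static heatmap PNG; row order is input order, no clustering."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(6, 4))
    data = matrix.matrix
    extent = [matrix.offsets[0], matrix.offsets[-1], data.shape[0], 0]
    ax.imshow(data, aspect="auto", interpolation="nearest", extent=extent, cmap="viridis")
    ax.set_xlabel("offset from motif center (bp)")
    if isinstance(matrix, VPlotMatrix):
        ax.set_ylabel("fragment length (bp)")
        ax.set_yticks(np.linspace(0, data.shape[0], 5))
        ax.set_yticklabels(
            np.linspace(matrix.lengths[0], matrix.lengths[-1], 5).astype(int)
        )
    else:
        ax.set_ylabel("site")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
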