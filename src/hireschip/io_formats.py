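"""Reading and writing of fragment, site, and track data.

All coordinates are 0-based half-open (BED convention) internally; BAM's
internal representation is converted at the boundary by pysam. A paired-end
mate pair is collapsed to its outer span — the sequenced insert — because
the insert, not the individual reads, is the protein-protected fragment.
"""

from __future__ import annotations

import logging
import os
from dataclasses import dataclass, field
from typing import Iterable, Iterator, Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)


class FormatError(ValueError):
    """A record in an input file violates its format."""


class EmptyInputError(ValueError):
    """Ingestion retained zero fragments."""


@dataclass(frozen=True)
class GenomeInfo:
    """Chromosome names and lengths; the genome size is their sum."""

    chrom_lengths: Mapping[str, int]

    def __post_init__(self) -> None:
        if not self.chrom_lengths:
            raise ValueError("GenomeInfo requires at least one chromosome")
        for name, length in self.chrom_lengths.items():
            if length <= 0:
                raise ValueError(f"chromosome {name!r} has non-positive length {length}")

    @property
    def genome_size(self) -> int:
        return int(sum(self.chrom_lengths.values()))

    def __contains__(self, chrom: str) -> bool:
        return chrom in self.chrom_lengths

    def length_of(self, chrom: str) -> int:
        return int(self.chrom_lengths[chrom])


@dataclass(frozen=True)
class Fragment:
    """A sequenced protein-protected DNA interval, 0-based half-open."""

    chrom: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if self.start < 0 or self.end <= self.start:
            raise ValueError(
                f"invalid fragment {self.chrom}:[{self.start},{self.end})"
            )

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass(frozen=True)
class MotifSite:
    """A stranded anchor interval (e.g. a 19-bp CTCF motif).

    The anchor coordinate ``center`` is ``start + (width - 1) // 2``: for a
    19-bp motif at [start, start+19), center = start + 9. For even widths
    the left-of-center base is used.
    """

    chrom: str
    start: int
    end: int
    name: str = "."
    strand: str = "+"

    def __post_init__(self) -> None:
        if self.end - self.start < 1:
            raise ValueError(
                f"site {self.chrom}:[{self.start},{self.end}) has width < 1"
            )
        if self.strand not in ("+", "-"):
            raise ValueError(f"strand must be '+' or '-', got {self.strand!r}")

    @property
    def width(self) -> int:
        return self.end - self.start

    @property
    def center(self) -> int:
        return self.start + (self.end - self.start - 1) // 2


class FragmentSet:
    """An ordered collection of fragments with ingestion bookkeeping.

    ``n_total_mapped`` is the count retained at ingestion, before any
    size-class filtering: it is the denominator of coverage normalization
    and is preserved through filters. ``provenance`` is a free-text log of
    the source and every filter applied.
    """

    def __init__(
        self,
        fragments: Iterable[Fragment] | pd.DataFrame,
        n_total_mapped: int | None = None,
        provenance: Sequence[str] = (),
        *,
        sort: bool = True,
    ) -> None:
        if isinstance(fragments, pd.DataFrame):
            df = fragments[["chrom", "start", "end"]].copy()
        else:
            frags = list(fragments)
            df = pd.DataFrame(
                {
                    "chrom": [f.chrom for f in frags],
                    "start": np.asarray([f.start for f in frags], dtype=np.int64),
                    "end": np.asarray([f.end for f in frags], dtype=np.int64),
                }
            )
        if len(df) and ((df["start"] < 0) | (df["end"] <= df["start"])).any():
            bad = df[(df["start"] < 0) | (df["end"] <= df["start"])].iloc[0]
            raise ValueError(
                f"invalid fragment {bad['chrom']}:[{bad['start']},{bad['end']})"
            )
        if sort and len(df):
            df = df.sort_values(["chrom", "start", "end"], kind="mergesort")
        df = df.reset_index(drop=True)
        df["start"] = df["start"].astype(np.int64)
        df["end"] = df["end"].astype(np.int64)
        self.df = df
        self.n_total_mapped = len(df) if n_total_mapped is None else int(n_total_mapped)
        if self.n_total_mapped < len(df):
            raise ValueError("n_total_mapped cannot be below the fragment count")
        self.provenance: list[str] = list(provenance)

    def __len__(self) -> int:
        return len(self.df)

    def __iter__(self) -> Iterator[Fragment]:
        for row in self.df.itertuples(index=False):
            yield Fragment(row.chrom, int(row.start), int(row.end))

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, FragmentSet):
            return NotImplemented
        return self.df.equals(other.df)

    @property
    def lengths(self) -> np.ndarray:
        return (self.df["end"] - self.df["start"]).to_numpy()

    @property
    def chroms(self) -> list[str]:
        return sorted(self.df["chrom"].unique().tolist())

    def for_chrom(self, chrom: str) -> tuple[np.ndarray, np.ndarray]:
        """(starts, ends) arrays of the fragments on one chromosome."""
        sub = self.df[self.df["chrom"] == chrom]
        return sub["start"].to_numpy(), sub["end"].to_numpy()

    def with_fragments(self, df: pd.DataFrame, note: str) -> "FragmentSet":
        """A derived set sharing this set's n_total_mapped, with a log entry."""
        return FragmentSet(
            df, n_total_mapped=self.n_total_mapped,
            provenance=[*self.provenance, note], sort=False,
        )


def read_chrom_sizes(path: str | os.PathLike) -> GenomeInfo:
    """Read a two-column name/length table into a GenomeInfo."""
    lengths: dict[str, int] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            if not line.strip() or line.startswith("#"):
                continue
            parts = line.split()
            if len(parts) < 2:
                raise FormatError(f"{path}:{lineno}: expected 'name length'")
            name = parts[0]
            if name in lengths:
                raise FormatError(f"{path}:{lineno}: duplicate chromosome {name!r}")
            try:
                lengths[name] = int(parts[1])
            except ValueError as exc:
                raise FormatError(f"{path}:{lineno}: bad length {parts[1]!r}") from exc
    return GenomeInfo(lengths)


def _sniff_format(path: str) -> str:
    ext = os.path.splitext(str(path))[1].lower()
    if ext == ".bam":
        return "bam"
    if ext == ".bedpe":
        return "bedpe"
    if ext == ".bed":
        # could still be BEDPE content; check the first data line
        pass
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split()
            if len(parts) >= 6:
                try:
                    int(parts[4])
                    int(parts[5])
                except ValueError:
                    return "bed"
                # columns 2,3 ints and 5,6 ints with col 4 a name: BEDPE
                return "bedpe"
            return "bed"
    return "bed"


def _read_bed_fragments(path: str) -> tuple[pd.DataFrame, int]:
    rows_c, rows_s, rows_e = [], [], []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            if not line.strip() or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split()
            if len(parts) < 3:
                raise FormatError(f"{path}:{lineno}: expected >= 3 BED columns")
            try:
                s, e = int(parts[1]), int(parts[2])
            except ValueError as exc:
                raise FormatError(f"{path}:{lineno}: non-integer coordinates") from exc
            if e <= s or s < 0:
                raise FormatError(f"{path}:{lineno}: invalid interval [{s},{e})")
            rows_c.append(parts[0])
            rows_s.append(s)
            rows_e.append(e)
    df = pd.DataFrame({"chrom": rows_c, "start": rows_s, "end": rows_e})
    return df, 0


def _read_bedpe_fragments(path: str) -> tuple[pd.DataFrame, int]:
    rows_c, rows_s, rows_e = [], [], []
    discordant = 0
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            if not line.strip() or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split()
            if len(parts) < 6:
                raise FormatError(f"{path}:{lineno}: expected >= 6 BEDPE columns")
            c1, c2 = parts[0], parts[3]
            try:
                s1, e1, s2, e2 = int(parts[1]), int(parts[2]), int(parts[4]), int(parts[5])
            except ValueError as exc:
                raise FormatError(f"{path}:{lineno}: non-integer coordinates") from exc
            if c1 != c2 or c1 == "." or c2 == ".":
                discordant += 1
                continue
            s, e = min(s1, s2), max(e1, e2)
            if e <= s or s < 0:
                raise FormatError(f"{path}:{lineno}: invalid span [{s},{e})")
            rows_c.append(c1)
            rows_s.append(s)
            rows_e.append(e)
    df = pd.DataFrame({"chrom": rows_c, "start": rows_s, "end": rows_e})
    return df, discordant


def _read_bam_fragments(path: str, mapq_min: int) -> tuple[pd.DataFrame, int]:
    import pysam

    rows_c, rows_s, rows_e = [], [], []
    discordant = 0
    with pysam.AlignmentFile(str(path)) as bam:
        for read in bam.fetch(until_eof=True):
            if not read.is_paired or not read.is_read1 or read.is_secondary or read.is_supplementary:
                continue
            if (
                read.is_unmapped
                or read.mate_is_unmapped
                or read.reference_id != read.next_reference_id
                or read.mapping_quality < mapq_min
                or read.template_length == 0
            ):
                discordant += 1
                continue
            left = min(read.reference_start, read.next_reference_start)
            span = abs(read.template_length)
            rows_c.append(read.reference_name)
            rows_s.append(left)
            rows_e.append(left + span)
    df = pd.DataFrame({"chrom": rows_c, "start": rows_s, "end": rows_e})
    return df, discordant


def read_fragments(
    path: str | os.PathLike,
    format_hint: str = "auto",
    mapq_min: int = 20,
    genome: GenomeInfo | None = None,
) -> FragmentSet:
    """Ingest fragments from BED3, BEDPE, or a paired-end BAM.

    Each proper mate pair on one chromosome becomes one fragment spanning
    the outer extent of the two mates; 3-column BED rows are taken verbatim.
    Discordant pairs (different chromosomes, unmapped mate, mapping quality
    below ``mapq_min``) are discarded and counted in the provenance log.
    """
    path = str(path)
    fmt = format_hint if format_hint != "auto" else _sniff_format(path)
    if fmt == "bed":
        df, discordant = _read_bed_fragments(path)
    elif fmt == "bedpe":
        df, discordant = _read_bedpe_fragments(path)
    elif fmt == "bam":
        df, discordant = _read_bam_fragments(path, mapq_min)
    else:
        raise ValueError(f"unknown format hint {fmt!r}")
    if genome is not None and len(df):
        unknown = set(df["chrom"]) - set(genome.chrom_lengths)
        if unknown:
            raise FormatError(f"{path}: chromosomes not in genome: {sorted(unknown)}")
    if not len(df):
        raise EmptyInputError(f"{path}: zero fragments retained")
    prov = [f"read {len(df)} fragments from {path} (format={fmt}, discarded={discordant})"]
    fs = FragmentSet(df, n_total_mapped=len(df), provenance=prov)
    fs.n_discarded = discordant
    return fs


def read_sites(path: str | os.PathLike) -> list[MotifSite]:
    """Read anchor sites from a BED3/BED6 file.

    Rows without a strand column default to "+" (logged once).
    """
    sites: list[MotifSite] = []
    defaulted = 0
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            if not line.strip() or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split()
            if len(parts) < 3:
                raise FormatError(f"{path}:{lineno}: expected >= 3 BED columns")
            try:
                s, e = int(parts[1]), int(parts[2])
            except ValueError as exc:
                raise FormatError(f"{path}:{lineno}: non-integer coordinates") from exc
            if e <= s:
                raise FormatError(f"{path}:{lineno}: end <= start ({s}, {e})")
            name = parts[3] if len(parts) > 3 else "."
            if len(parts) >= 6 and parts[5] in ("+", "-"):
                strand = parts[5]
            else:
                strand = "+"
                defaulted += 1
            sites.append(MotifSite(parts[0], s, e, name=name, strand=strand))
    if defaulted:
        logger.warning("%s: %d site(s) without strand defaulted to '+'", path, defaulted)
    return sites


def write_track(track, path: str | os.PathLike) -> None:
    """Write a coverage track as run-length-encoded bedGraph.

    Adjacent equal values are merged into one line; zero-valued runs are
    omitted. Integer counts round-trip exactly; normalized values to
    better than 1e-9 relative error.
    """
    is_int = track.scale == "raw_counts"
    with open(path, "w") as fh:
        for chrom in sorted(track.values):
            vals = track.values[chrom]
            if not len(vals):
                continue
            # run boundaries where the value changes
            change = np.flatnonzero(vals[1:] != vals[:-1]) + 1
            starts = np.concatenate(([0], change))
            ends = np.concatenate((change, [len(vals)]))
            for s, e in zip(starts, ends):
                v = vals[s]
                if v == 0:
                    continue
                if is_int:
                    fh.write(f"{chrom}\t{s}\t{e}\t{int(v)}\n")
                else:
                    fh.write(f"{chrom}\t{s}\t{e}\t{float(v):.12g}\n")


def read_track(path: str | os.PathLike, genome: GenomeInfo, scale: str = "raw_counts"):
    """Read a bedGraph into a CoverageTrack over ``genome`` (zeros elsewhere)."""
    from hireschip.coverage import CoverageTrack

    dtype = np.int64 if scale == "raw_counts" else np.float64
    values = {c: np.zeros(n, dtype=dtype) for c, n in genome.chrom_lengths.items()}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            if not line.strip() or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split()
            if len(parts) < 4:
                raise FormatError(f"{path}:{lineno}: expected 4 bedGraph columns")
            chrom, s, e, v = parts[0], int(parts[1]), int(parts[2]), float(parts[3])
            if chrom not in values:
                raise FormatError(f"{path}:{lineno}: unknown chromosome {chrom!r}")
            values[chrom][s:e] = int(v) if scale == "raw_counts" else v
    return CoverageTrack(values=values, genome=genome, scale=scale)
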