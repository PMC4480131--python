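"""Per-site resolution statistics.

Half-height width: for the signal within +-flank bp of a site, find the
maximum, estimate a local background as the median over the two outermost
bg_margin windows, and report the number of contiguous base pairs, in the
run containing the maximum, with signal at or above half the maximum.
Narrower widths mean sharper peaks, i.e. higher positional resolution.

The half-height threshold is max/2 on the given signal. Expressing the
signal as a fold over its (positive) background before halving selects the
same set of offsets, because dividing by a positive scalar preserves the
">= half of max" relation; the background is retained for QC. An
alternative midpoint-between-background-and-max threshold is available via
``threshold_mode="midrise"``.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from hireschip.io_formats import MotifSite
from hireschip.motif_profiles import EndProfile, ProfileMatrix


@dataclass(frozen=True)
class HalfHeightResult:
    site_id: str
    max_value: float
    max_offset: int
    background: float
    width: int
    qc_flag: str  # ok | flat | zero_background


@dataclass(frozen=True)
class PeakPairResult:
    left_peak_offset: int | None
    right_peak_offset: int | None
    separation: int | None
    n_predominant_peaks: int
    straddles_center: bool = True


def _lower_median(values: np.ndarray) -> float:
    """Median with the lower-of-two convention for even counts."""
    v = np.sort(np.asarray(values, dtype=np.float64))
    return float(v[(len(v) - 1) // 2])


def half_height_width(
    signal: np.ndarray,
    flank: int = 1000,
    bg_margin: int = 100,
    site_id: str = ".",
    threshold_mode: str = "half_max",
) -> HalfHeightResult:
    """Half-height peak width of one site's +-flank signal window.

    ``signal`` must span exactly 2*flank+1 offsets (-flank..+flank). The
    width is the length of the maximal contiguous run of offsets with
    signal >= threshold that contains the (leftmost) argmax.
    """
    signal = np.asarray(signal, dtype=np.float64)
    if len(signal) != 2 * flank + 1:
        raise ValueError(
            f"signal spans {len(signal)} offsets; expected {2 * flank + 1} for flank {flank}"
        )
    if not 0 < bg_margin < flank:
        raise ValueError("bg_margin must satisfy 0 < bg_margin < flank")

    imax = int(np.argmax(signal))  # leftmost argmax
    max_value = float(signal[imax])
    background = _lower_median(
        np.concatenate((signal[:bg_margin], signal[-bg_margin:]))
    )

    if threshold_mode == "half_max":
        threshold = max_value / 2.0
    elif threshold_mode == "midrise":
        threshold = background + (max_value - background) / 2.0
    else:
        raise ValueError(f"unknown threshold_mode {threshold_mode!r}")

    above = signal >= threshold
    # run containing the maximum
    lo = imax
    while lo > 0 and above[lo - 1]:
        lo -= 1
    hi = imax
    while hi < len(signal) - 1 and above[hi + 1]:
        hi += 1
    width = hi - lo + 1

    if np.all(signal == signal[0]):
        qc = "flat"
    elif background <= 0:
        qc = "zero_background"
    else:
        qc = "ok"

    return HalfHeightResult(
        site_id=site_id,
        max_value=max_value,
        max_offset=imax - flank,
        background=background,
        width=width,
        qc_flag=qc,
    )


def half_height_widths(
    matrix: ProfileMatrix,
    flank: int | None = None,
    bg_margin: int = 100,
    threshold_mode: str = "half_max",
) -> tuple[list[HalfHeightResult], dict[str, float]]:
    """Per-site widths for every row of a profile matrix, plus summary
    quartiles (q1/median/q3, over sites flagged ok or zero_background)."""
    flank = matrix.flank if flank is None else flank
    results = [
        half_height_width(row, flank=flank, bg_margin=bg_margin,
                          site_id=sid, threshold_mode=threshold_mode)
        for sid, row in zip(matrix.site_ids, matrix.matrix)
    ]
    widths = np.array([r.width for r in results if r.qc_flag != "flat"], dtype=float)
    if widths.size:
        q1, med, q3 = np.percentile(widths, [25, 50, 75])
        summary = {"n": int(widths.size), "q1": float(q1), "median": float(med), "q3": float(q3)}
    else:
        summary = {"n": 0, "q1": float("nan"), "median": float("nan"), "q3": float("nan")}
    return results, summary


def _local_maxima(counts: np.ndarray) -> np.ndarray:
    """Indices of strict-or-plateau local maxima (leftmost of each plateau)."""
    idx = []
    n = len(counts)
    i = 0
    while i < n:
        j = i
        while j + 1 < n and counts[j + 1] == counts[i]:
            j += 1
        left_ok = i == 0 or counts[i - 1] < counts[i]
        right_ok = j == n - 1 or counts[j + 1] < counts[i]
        if left_ok and right_ok and counts[i] > 0:
            idx.append(i)
        i = j + 1
    return np.asarray(idx, dtype=int)


def peak_pair_separation(
    profile: EndProfile,
    source: str = "split",
    prominence_frac: float = 0.5,
    min_peak_distance: int = 5,
) -> PeakPairResult:
    """Offset distance between the left-end and right-end peaks.

    source="split": the left peak is the argmax of left-end counts and the
    right peak the argmax of right-end counts. source="combined": the two
    highest local maxima of the combined counts at least
    ``min_peak_distance`` apart. ``n_predominant_peaks`` counts local
    maxima with height >= prominence_frac * global max after merging
    maxima closer than ``min_peak_distance`` (keeping the higher).
    ``separation`` is defined only when the two peaks straddle offset 0.
    """
    offsets = profile.offsets
    combined = profile.combined
    if combined.sum() == 0:
        raise ValueError("end profile is all zero")

    if source == "split":
        if profile.left_counts.sum() == 0 or profile.right_counts.sum() == 0:
            raise ValueError("split mode requires non-zero left and right counts")
        li = int(np.argmax(profile.left_counts))
        ri = int(np.argmax(profile.right_counts))
        peaks_for_count = _merge_close(
            _local_maxima(combined), combined, min_peak_distance
        )
    else:
        if source != "combined":
            raise ValueError(f"unknown source {source!r}")
        maxima = _merge_close(_local_maxima(combined), combined, min_peak_distance)
        if len(maxima) < 2:
            left_off = int(offsets[maxima[0]]) if len(maxima) else None
            return PeakPairResult(
                left_peak_offset=left_off,
                right_peak_offset=None,
                separation=None,
                n_predominant_peaks=_count_predominant(maxima, combined, prominence_frac),
                straddles_center=False,
            )
        top2 = maxima[np.argsort(combined[maxima], kind="mergesort")[-2:]]
        li, ri = int(top2.min()), int(top2.max())
        peaks_for_count = maxima

    left_off = int(offsets[li])
    right_off = int(offsets[ri])
    straddles = left_off <= 0 <= right_off and left_off < right_off
    n_pred = _count_predominant(peaks_for_count, combined, prominence_frac)
    return PeakPairResult(
        left_peak_offset=left_off,
        right_peak_offset=right_off,
        separation=(right_off - left_off) if straddles else None,
        n_predominant_peaks=n_pred,
        straddles_center=straddles,
    )


def _merge_close(maxima: np.ndarray, counts: np.ndarray, min_dist: int) -> np.ndarray:
    """Merge local maxima closer than min_dist, keeping the higher of each pair."""
    if len(maxima) == 0:
        return maxima
    kept: list[int] = [int(maxima[0])]
    for m in maxima[1:]:
        if m - kept[-1] < min_dist:
            if counts[m] > counts[kept[-1]]:
                kept[-1] = int(m)
        else:
            kept.append(int(m))
    return np.asarray(kept, dtype=int)


def _count_predominant(maxima: np.ndarray, counts: np.ndarray, frac: float) -> int:
    if len(maxima) == 0:
        return 0
    cutoff = frac * counts.max()
    return int(np.count_nonzero(counts[maxima] >= cutoff))


def motif_spacing_filter(
    sites: Sequence[MotifSite], min_sep: int = 500
) -> list[MotifSite]:
    """Retain sites whose nearest same-chromosome neighbor is >= min_sep away.

    Distances are center-to-center and evaluated against the ORIGINAL input
    set, so a crowded cluster removes all of its members. Sites on
    different chromosomes never conflict. Idempotent: the retained set has
    no pair closer than min_sep, so filtering again changes nothing.
    """
    by_chrom: dict[str, list[tuple[int, int]]] = {}
    for i, s in enumerate(sites):
        by_chrom.setdefault(s.chrom, []).append((s.center, i))
    keep = np.ones(len(sites), dtype=bool)
    for entries in by_chrom.values():
        entries.sort()
        centers = np.array([c for c, _ in entries])
        for k, (c, i) in enumerate(entries):
            nearest = np.inf
            if k > 0:
                nearest = min(nearest, c - centers[k - 1])
            if k < len(centers) - 1:
                nearest = min(nearest, centers[k + 1] - c)
            if nearest < min_sep:
                keep[i] = False
    return [s for i, s in enumerate(sites) if keep[i]]


def results_to_tsv(results: Sequence[HalfHeightResult], path) -> None:
    with open(path, "w") as fh:
        fh.write("site_id\tmax_value\tmax_offset\tbackground\twidth\tqc_flag\n")
        for r in results:
            fh.write(
                f"{r.site_id}\t{r.max_value:.12g}\t{r.max_offset}\t"
                f"{r.background:.12g}\t{r.width}\t{r.qc_flag}\n"
            )
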