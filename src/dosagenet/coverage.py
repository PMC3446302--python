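"""Gene-dose confirmation from DNA-seq coverage.

Reads-per-million over deleted regions, wild-type vs deficiency fold
differences, and a windowed scan for unannotated deletions. In a Df/+
heterozygote the deleted segment retains one of two copies, so wild-type
coverage is expected to be two-fold higher over the segment; the scan
flags runs of windows whose Df/wild-type RPM ratio falls below a threshold
midway (in log space) between the one-dose and two-dose expectations.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .containers import CoverageTrack, to_internal


@dataclass(frozen=True)
class RegionDoseEstimate:
    """RPM pair and fold difference for one region (1-based inclusive)."""

    chrom: str
    first: int
    last: int
    rpm_df: float
    rpm_wt: float
    fold_difference: float  # rpm_wt / rpm_df; NaN if fully absent
    label: str = ""

    @property
    def fully_absent(self) -> bool:
        return self.rpm_df == 0.0


def region_rpm(track: CoverageTrack, first: int, last: int) -> float:
    """Reads per million over [first, last], pro-rating partial bins.

    A bin overlapping the region by a fraction f contributes f of its
    counts, i.e. reads are treated as uniform within a bin.
    """
    if track.total_reads <= 0:
        raise ValueError("track has zero total mapped reads")
    start, end = to_internal(first, last)
    if end > track.chrom_length:
        raise ValueError("region extends beyond chromosome")
    b = track.bin_size
    bin_lo = np.arange(track.n_bins) * b
    bin_hi = np.minimum(bin_lo + b, track.chrom_length)
    overlap = np.clip(np.minimum(bin_hi, end) - np.maximum(bin_lo, start), 0, None)
    frac = overlap / (bin_hi - bin_lo)
    reads = float((track.counts * frac).sum())
    return reads * 1e6 / track.total_reads


def fold_difference(
    df_track_rpm: float,
    wt_track_rpm: float,
    chrom: str = "",
    first: int = 1,
    last: int = 1,
    label: str = "",
) -> RegionDoseEstimate:
    """Wild-type over deficiency RPM ratio for one region."""
    if df_track_rpm < 0 or wt_track_rpm < 0:
        raise ValueError("RPM values must be non-negative")
    fold = np.nan if df_track_rpm == 0 else wt_track_rpm / df_track_rpm
    return RegionDoseEstimate(chrom, first, last, df_track_rpm, wt_track_rpm, fold, label)


def region_dose_estimate(
    df_track: CoverageTrack,
    wt_track: CoverageTrack,
    first: int,
    last: int,
    label: str = "",
) -> RegionDoseEstimate:
    """RPM in both tracks plus their fold difference over one region."""
    return fold_difference(
        region_rpm(df_track, first, last),
        region_rpm(wt_track, first, last),
        chrom=df_track.chrom,
        first=first,
        last=last,
        label=label,
    )


def summarize_dose_table(estimates: list[RegionDoseEstimate]) -> dict[str, float]:
    """Arithmetic mean and sample SD (n-1) of the fold differences."""
    folds = np.array([e.fold_difference for e in estimates if np.isfinite(e.fold_difference)])
    if len(folds) < 2:
        raise ValueError("need >= 2 fold differences to summarize")
    return {"mean": float(folds.mean()), "sd": float(folds.std(ddof=1)), "n": len(folds)}


def scan_novel_deletions(
    df_track: CoverageTrack,
    wt_track: CoverageTrack,
    window: int = 5,
    ratio_threshold: float = 0.66,
    mask: list[tuple[int, int]] | None = None,
) -> list[tuple[int, int]]:
    """Windowed scan for unannotated one-dose segments.

    Slides a ``window``-bin window; windows whose Df/WT RPM ratio is
    <= ``ratio_threshold`` (default 0.66, the log-space midpoint between
    dose 1 and dose 2) are merged into maximal runs, reported as 1-based
    inclusive intervals.  ``mask`` intervals (e.g. known engineered
    deletions, selectively endoreplicated loci) are excluded.  Resolution
    is window-limited: deletions much shorter than the window dilute below
    threshold and can be missed.
    """
    if df_track.bin_size != wt_track.bin_size or df_track.n_bins != wt_track.n_bins:
        raise ValueError("tracks must share binning")
    if window < 1:
        raise ValueError("window must be >= 1")
    n = df_track.n_bins
    if window > n:
        raise ValueError("window larger than track")
    kernel = np.ones(window)
    df_win = np.convolve(df_track.counts / df_track.total_reads, kernel, mode="valid")
    wt_win = np.convolve(wt_track.counts / wt_track.total_reads, kernel, mode="valid")
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = np.where(wt_win > 0, df_win / wt_win, np.inf)
    low = ratio <= ratio_threshold

    intervals: list[tuple[int, int]] = []
    b = df_track.bin_size
    i = 0
    while i < len(low):
        if low[i]:
            j = i
            while j + 1 < len(low) and low[j + 1]:
                j += 1
            # windows i..j -> bins i .. j+window-1
            first = i * b + 1
            last = min((j + window) * b, df_track.chrom_length)
            intervals.append((first, last))
            i = j + 1
        else:
            i += 1
    if mask:
        intervals = [
            (f, l)
            for f, l in intervals
            if not any(f <= m_l and m_f <= l for m_f, m_l in mask)
        ]
    return intervals


def dose_table(
    estimates_by_sex: dict[str, list[RegionDoseEstimate]]
) -> pd.DataFrame:
    """Tabular report with 2-decimal folds, one row per (region, sex)."""
    rows = []
    for sex, ests in estimates_by_sex.items():
        for e in ests:
            rows.append(
                {
                    "Deficiency": e.label,
                    "First missing base": e.first,
                    "Last missing base": e.last,
                    "Measured in": sex.capitalize(),
                    "RPM in Df region": round(e.rpm_df, 1),
                    "RPM in WT": round(e.rpm_wt, 1),
                    "Fold difference": round(e.fold_difference, 2),
                }
            )
    return pd.DataFrame(rows)


def load_published_dose_table() -> pd.DataFrame:
    """The published DNA-seq dose table for the 21 DrosDel 2L deficiencies
    plus the de novo Hsp60c deletion (44 rows: 22 regions x 2 sexes), with
    the breakpoints, per-sex RPM values and printed fold differences."""
    ref = importlib.resources.files("dosagenet") / "data" / "dnaseq_segments.tsv"
    with importlib.resources.as_file(ref) as path:
        return pd.read_csv(path, sep="\t")


def write_bedgraph(track: CoverageTrack, path) -> None:
    """bedGraph (0-based half-open) with one row per bin."""
    b = track.bin_size
    with open(path, "w") as fh:
        for i, c in enumerate(track.counts):
            lo = i * b
            hi = min(lo + b, track.chrom_length)
            fh.write(f"{track.chrom}\t{lo}\t{hi}\t{c:g}\n")


def read_bedgraph(path, bin_size: int, chrom_length: int) -> CoverageTrack:
    """Read a single-chromosome bedGraph produced on a fixed binning."""
    df = pd.read_csv(path, sep="\t", names=["chrom", "start", "end", "count"])
    if df["chrom"].nunique() != 1:
        raise ValueError("expected a single-chromosome bedGraph")
    n_bins = -(-chrom_length // bin_size)
    counts = np.zeros(n_bins)
    counts[df["start"] // bin_size] = df["count"]
    return CoverageTrack(df["chrom"].iloc[0], bin_size, counts, chrom_length)
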