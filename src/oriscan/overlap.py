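"""Interval-vs-interval analytics for an origin catalogue.

Covers genic annotation (TSS / exon / intron / intergenic), replication-
timing profiles, inter-origin spacing histograms and nested-window overlap
with compositional-skew jumps.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core import FeatureTrack, overlaps_any
from .catalog import OriginSet

TIMING_CLASSES = ["S1", "S2", "S3", "S4", "S5", "S6"]
DEFAULT_JUMP_WINDOWS = (2_000, 4_000, 6_000, 10_000, 20_000, 30_000, 40_000)
CATEGORIES = ["TSS", "exon", "intron", "intergenic"]


@dataclass
class AnnotationResult:
    categories: pd.Series            # per-origin category, index-aligned
    counts: pd.Series                # per-category counts
    fractions: pd.Series             # per-category fractions

    def to_dict(self) -> dict:
        return {
            "counts": self.counts.to_dict(),
            "fractions": self.fractions.to_dict(),
        }


def expand_tss(tss: FeatureTrack, halfwidth: int) -> pd.DataFrame:
    """Symmetric windows around TSS points (midpoint of each record)."""
    mid = (tss.df["start"] + tss.df["end"]) // 2
    return pd.DataFrame(
        {
            "chrom": tss.df["chrom"],
            "start": np.maximum(mid - halfwidth, 0),
            "end": mid + halfwidth,
        }
    )


def annotate_origins(
    origins: OriginSet,
    genes: FeatureTrack,
    tss: FeatureTrack,
    exons: FeatureTrack,
    tss_halfwidth: int = 500,
) -> AnnotationResult:
    """Single-category genic annotation with priority TSS > exon > intron.

    An origin overlapping a TSS window (+/- ``tss_halfwidth`` around the
    start site) is TSS regardless of what else it touches; otherwise exon
    beats intron (overlap with a gene body but no exon); anything left is
    intergenic.
    """
    df = origins.df
    tss_win = expand_tss(tss, tss_halfwidth)
    is_tss = overlaps_any(df, tss_win)
    is_exon = overlaps_any(df, exons.df) & ~is_tss
    is_genic = overlaps_any(df, genes.df)
    is_intron = is_genic & ~is_tss & ~is_exon
    cat = np.full(len(df), "intergenic", dtype=object)
    cat[is_intron] = "intron"
    cat[is_exon] = "exon"
    cat[is_tss] = "TSS"
    categories = pd.Series(cat, index=df.index)
    counts = categories.value_counts().reindex(CATEGORIES, fill_value=0)
    total = max(len(df), 1)
    return AnnotationResult(categories, counts, counts / total)


@dataclass
class TimingProfile:
    counts: pd.Series      # per class S1..S6
    percentages: pd.Series  # may sum to >100 because windows overlap
    unassigned: int        # origins overlapping no timing window

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"count": self.counts, "percent": self.percentages}
        ).rename_axis("timing_class")


def timing_profile(origins: OriginSet, timing: FeatureTrack) -> TimingProfile:
    """Fraction of origins overlapping each replication-timing class.

    An origin straddling a window boundary counts in every class it touches,
    so the per-class percentages can exceed 100 in total.
    """
    df = origins.df
    counts = {}
    any_hit = np.zeros(len(df), dtype=bool)
    for cls in TIMING_CLASSES:
        sub = timing.df[timing.df["name"] == cls]
        hit = overlaps_any(df, sub) if len(sub) else np.zeros(len(df), bool)
        counts[cls] = int(hit.sum())
        any_hit |= hit
    counts_s = pd.Series(counts)
    total = max(len(df), 1)
    return TimingProfile(counts_s, 100.0 * counts_s / total, int((~any_hit).sum()))


@dataclass
class DistanceHistogram:
    bin_width: int
    counts: np.ndarray     # counts per half-open bin [k*bin, (k+1)*bin)
    n_distances: int

    def fraction(self, bin_index: int) -> float:
        if self.n_distances == 0:
            return 0.0
        if bin_index >= len(self.counts):
            return 0.0
        return float(self.counts[bin_index]) / self.n_distances


def inter_origin_distances(
    origins: OriginSet, bin_width: int = 5_000, method: str = "midpoint"
) -> DistanceHistogram:
    """Histogram of successive inter-origin distances per chromosome.

    Distances are midpoint-to-midpoint by default (``method="edge"`` gives
    nearest-edge gaps); chromosomes with fewer than two origins contribute
    nothing.
    """
    if bin_width <= 0:
        raise ValueError("bin_width must be positive")
    dists: list[np.ndarray] = []
    for _, sub in origins.df.groupby("chrom", sort=False):
        if len(sub) < 2:
            continue
        if method == "midpoint":
            pos = np.sort(((sub["start"] + sub["end"]) // 2).to_numpy())
            d = np.diff(pos)
        elif method == "edge":
            sub = sub.sort_values("start")
            d = np.maximum(sub["start"].to_numpy()[1:] - sub["end"].to_numpy()[:-1], 0)
        else:
            raise ValueError(f"unknown distance method {method!r}")
        dists.append(d)
    if not dists:
        return DistanceHistogram(bin_width, np.zeros(0, dtype=np.int64), 0)
    all_d = np.concatenate(dists)
    n_bins = int(all_d.max() // bin_width) + 1
    counts = np.bincount(all_d // bin_width, minlength=n_bins)
    return DistanceHistogram(bin_width, counts.astype(np.int64), int(len(all_d)))


def jump_overlap_profile(
    origins: OriginSet,
    jumps: FeatureTrack,
    window_sizes: tuple[int, ...] = DEFAULT_JUMP_WINDOWS,
) -> pd.DataFrame:
    """Fraction of skew jumps with an origin within a nested set of windows.

    Each jump is collapsed to its midpoint nucleotide; for window size W the
    jump overlaps if [p - W/2, p + W/2) intersects any origin by >= 1 bp.
    Fractions are reported separately for + and - polarity and are
    monotone non-decreasing in W by construction.
    """
    rows = []
    jdf = jumps.df
    for polarity in ["+", "-"]:
        sub = jdf[jdf["strand"] == polarity]
        mid = ((sub["start"] + sub["end"]) // 2).to_numpy()
        for W in window_sizes:
            if len(sub) == 0:
                rows.append((polarity, W, 0, 0, 0.0))
                continue
            win = pd.DataFrame(
                {
                    "chrom": sub["chrom"].to_numpy(),
                    "start": np.maximum(mid - W // 2, 0),
                    "end": mid + W // 2,
                }
            )
            hit = overlaps_any(win, origins.df)
            rows.append((polarity, W, len(sub), int(hit.sum()),
                         float(hit.mean())))
    return pd.DataFrame(
        rows, columns=["polarity", "window_size", "n_jumps", "n_overlap", "fraction"]
    )
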