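"""Replicate-intersect origin catalogue and its summary statistics."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .core import GenomeModel, ReadLibrary, merge_intervals, overlaps_any, intersect_pair


@dataclass
class OriginSet:
    """The origin catalogue: non-overlapping enriched intervals found in both
    replicates, with optional per-replicate supporting tag counts."""

    df: pd.DataFrame  # chrom, start, end [, tags_a, tags_b]
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        df = self.df.copy()
        df["start"] = df["start"].astype(np.int64)
        df["end"] = df["end"].astype(np.int64)
        self.df = df.reset_index(drop=True)
        if len(df) and (df["end"] <= df["start"]).any():
            raise ValueError("origin with non-positive width")

    def __len__(self) -> int:
        return len(self.df)

    @property
    def widths(self) -> np.ndarray:
        return (self.df["end"] - self.df["start"]).to_numpy()


def intersect_replicates(a: pd.DataFrame, b: pd.DataFrame,
                         provenance: dict | None = None) -> OriginSet:
    """Base-pair intersection of two island sets, book-ended pieces merged.

    Every output interval is contained in at least one island of each
    replicate ("peaks present in both libraries").
    """
    pieces = intersect_pair(a, b)
    merged = merge_intervals(pieces, gap=0)
    return OriginSet(merged, provenance or {})


def count_reciprocal(a: pd.DataFrame, b: pd.DataFrame) -> tuple[int, int, int, int]:
    """Element-wise Venn counts at >=1 nt overlap.

    Returns (n_a_hit, n_a_only, n_b_hit, n_b_only).  Counts are per element,
    so the two "hit" totals are generally unequal (one broad interval can
    cover several on the other side).
    """
    a_hit = overlaps_any(a.reset_index(drop=True), b) if len(a) else np.zeros(0, bool)
    b_hit = overlaps_any(b.reset_index(drop=True), a) if len(b) else np.zeros(0, bool)
    return (
        int(a_hit.sum()),
        int(len(a) - a_hit.sum()),
        int(b_hit.sum()),
        int(len(b) - b_hit.sum()),
    )


@dataclass
class CatalogSummary:
    total: int
    per_chromosome: pd.Series           # counts incl. zero-count chromosomes
    width_quartiles: tuple[float, float, float] | None  # Q1, median, Q3
    width_quartiles_per_chrom: pd.DataFrame
    tags_per_origin: pd.DataFrame | None = None

    def to_dict(self) -> dict:
        q = self.width_quartiles
        return {
            "total_origins": self.total,
            "per_chromosome": self.per_chromosome.to_dict(),
            "width_q1": None if q is None else q[0],
            "width_median": None if q is None else q[1],
            "width_q3": None if q is None else q[2],
        }


def summarize_catalog(
    origins: OriginSet,
    genome: GenomeModel,
    lib_a: ReadLibrary | None = None,
    lib_b: ReadLibrary | None = None,
) -> CatalogSummary:
    """Per-chromosome counts and width quartiles (linear interpolation).

    If replicate libraries are given, tags-per-origin is recomputed by
    counting tag midpoints inside each final origin span, making the summary
    independent of caller internals.
    """
    df = origins.df
    counts = pd.Series(0, index=list(genome.chromosomes), dtype=int)
    if len(df):
        observed = df["chrom"].value_counts()
        counts.loc[observed.index] = observed
    if len(df) == 0:
        quart = None
        per_chrom_q = pd.DataFrame(columns=["chrom", "q1", "median", "q3"])
    else:
        w = origins.widths
        quart = tuple(float(x) for x in np.quantile(w, [0.25, 0.5, 0.75]))
        rows = []
        for chrom, sub in df.groupby("chrom", sort=False):
            cw = (sub["end"] - sub["start"]).to_numpy()
            q1, q2, q3 = np.quantile(cw, [0.25, 0.5, 0.75])
            rows.append((chrom, float(q1), float(q2), float(q3)))
        per_chrom_q = pd.DataFrame(rows, columns=["chrom", "q1", "median", "q3"])
    tags = None
    if lib_a is not None and lib_b is not None and len(df):
        tags = pd.DataFrame(
            {
                "tags_a": count_tags_in_spans(lib_a, df),
                "tags_b": count_tags_in_spans(lib_b, df),
            }
        )
    return CatalogSummary(
        total=len(df),
        per_chromosome=counts,
        width_quartiles=quart,
        width_quartiles_per_chrom=per_chrom_q,
        tags_per_origin=tags,
    )


def count_tags_in_spans(lib: ReadLibrary, spans: pd.DataFrame) -> np.ndarray:
    """Number of tag midpoints falling inside each span interval."""
    out = np.zeros(len(spans), dtype=np.int64)
    mids_by_chrom = {
        chrom: np.sort(((sub["start"] + sub["end"]) // 2).to_numpy())
        for chrom, sub in lib.df.groupby("chrom", sort=False)
    }
    for i, row in enumerate(spans.itertuples(index=False)):
        mids = mids_by_chrom.get(row.chrom)
        if mids is None:
            continue
        out[i] = np.searchsorted(mids, row.end, "left") - np.searchsorted(
            mids, row.start, "left"
        )
    return out
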