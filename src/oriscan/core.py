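"""Core genomic containers and interval primitives.

All coordinates throughout the package are 0-based half-open (BED
convention).  Interval collections are held as pandas DataFrames with
``chrom``, ``start``, ``end`` columns; strand is ``+``, ``-`` or ``.`` and is
ignored by overlap arithmetic (it matters only to the G4 scanner and to
read-tag shifting).
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

TRACK_COLUMNS = ["chrom", "start", "end", "name", "strand"]
TAG_COLUMNS = ["chrom", "start", "end", "strand"]


def stage_rng(seed: int, stage: str) -> np.random.Generator:
    """Independent, reproducible RNG stream for a named pipeline stage.

    A single user-facing seed is split per stage by hashing the stage name,
    so toggling one stochastic stage never shifts another stage's stream.
    """
    return np.random.default_rng(
        np.random.SeedSequence([int(seed) & 0x7FFFFFFF, zlib.crc32(stage.encode())])
    )


def _empty_track_df() -> pd.DataFrame:
    return pd.DataFrame(
        {
            "chrom": pd.Series(dtype=str),
            "start": pd.Series(dtype=np.int64),
            "end": pd.Series(dtype=np.int64),
            "name": pd.Series(dtype=str),
            "strand": pd.Series(dtype=str),
        }
    )


def as_track_df(df: pd.DataFrame | None) -> pd.DataFrame:
    """Coerce a partial interval frame to the canonical 5-column layout."""
    if df is None or len(df) == 0:
        return _empty_track_df()
    out = df.copy()
    if "name" not in out.columns:
        out["name"] = "."
    if "strand" not in out.columns:
        out["strand"] = "."
    out["start"] = out["start"].astype(np.int64)
    out["end"] = out["end"].astype(np.int64)
    return out[TRACK_COLUMNS].reset_index(drop=True)


@dataclass
class FeatureTrack:
    """A labelled collection of genomic intervals (a BED-style track)."""

    label: str
    df: pd.DataFrame = field(default_factory=_empty_track_df)

    def __post_init__(self) -> None:
        self.df = as_track_df(self.df)
        if len(self.df):
            bad = self.df["start"] >= self.df["end"]
            if bad.any():
                row = self.df[bad].iloc[0]
                raise ValueError(
                    f"track {self.label!r}: interval with start >= end "
                    f"({row['chrom']}:{row['start']}-{row['end']})"
                )
            if (self.df["start"] < 0).any():
                raise ValueError(f"track {self.label!r}: negative coordinate")

    def __len__(self) -> int:
        return len(self.df)

    def sorted(self, chrom_order: list[str] | None = None) -> "FeatureTrack":
        df = self.df
        if chrom_order is not None:
            key = {c: i for i, c in enumerate(chrom_order)}
            df = df.assign(_k=df["chrom"].map(key)).sort_values(
                ["_k", "start", "end"], kind="mergesort"
            ).drop(columns="_k")
        else:
            df = df.sort_values(["chrom", "start", "end"], kind="mergesort")
        return FeatureTrack(self.label, df.reset_index(drop=True))

    def validate_against(self, genome: "GenomeModel") -> None:
        for chrom, sub in self.df.groupby("chrom", sort=False):
            if chrom not in genome.chromosomes:
                raise ValueError(f"track {self.label!r}: unknown chromosome {chrom!r}")
            if (sub["end"] > genome.chromosomes[chrom]).any():
                raise ValueError(
                    f"track {self.label!r}: interval beyond end of {chrom}"
                )


@dataclass
class ReadLibrary:
    """Stranded read tags (one record per sequenced fragment) for one library."""

    name: str
    df: pd.DataFrame = field(default_factory=_empty_track_df)

    def __post_init__(self) -> None:
        if self.df is None or len(self.df) == 0:
            self.df = pd.DataFrame(
                {
                    "chrom": pd.Series(dtype=str),
                    "start": pd.Series(dtype=np.int64),
                    "end": pd.Series(dtype=np.int64),
                    "strand": pd.Series(dtype=str),
                }
            )
        else:
            df = self.df.copy()
            if "strand" not in df.columns:
                df["strand"] = "."
            df["start"] = df["start"].astype(np.int64)
            df["end"] = df["end"].astype(np.int64)
            self.df = df[TAG_COLUMNS].reset_index(drop=True)
            if (self.df["start"] >= self.df["end"]).any():
                raise ValueError(f"library {self.name!r}: tag with start >= end")

    @property
    def total_tags(self) -> int:
        return len(self.df)

    def __len__(self) -> int:
        return len(self.df)


@dataclass
class GenomeModel:
    """Chromosome lengths, optional sequences, and named annotation tracks."""

    chromosomes: dict[str, int]
    sequences: dict[str, str] | None = None
    tracks: dict[str, FeatureTrack] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name, length in self.chromosomes.items():
            if length <= 0:
                raise ValueError(f"chromosome {name!r} has non-positive length")

    @property
    def total_length(self) -> int:
        return int(sum(self.chromosomes.values()))

    def add_track(self, track: FeatureTrack) -> None:
        track.validate_against(self)
        self.tracks[track.label] = track.sorted(list(self.chromosomes))


# ---------------------------------------------------------------------------
# Interval arithmetic on plain DataFrames
# ---------------------------------------------------------------------------

def merge_intervals(df: pd.DataFrame, gap: int = 0) -> pd.DataFrame:
    """Merge intervals closer than or equal to ``gap`` bp (0 = book-ended).

    Returns a sorted frame of disjoint intervals; extra columns are dropped.
    """
    if len(df) == 0:
        return df.loc[:, ["chrom", "start", "end"]].copy()
    out_chrom: list[str] = []
    out_start: list[int] = []
    out_end: list[int] = []
    for chrom, sub in df.sort_values(["chrom", "start", "end"]).groupby(
        "chrom", sort=True
    ):
        starts = sub["start"].to_numpy()
        ends = sub["end"].to_numpy()
        cur_s, cur_e = int(starts[0]), int(ends[0])
        for s, e in zip(starts[1:], ends[1:]):
            if s - cur_e <= gap:
                cur_e = max(cur_e, int(e))
            else:
                out_chrom.append(chrom)
                out_start.append(cur_s)
                out_end.append(cur_e)
                cur_s, cur_e = int(s), int(e)
        out_chrom.append(chrom)
        out_start.append(cur_s)
        out_end.append(cur_e)
    return pd.DataFrame(
        {
            "chrom": out_chrom,
            "start": np.asarray(out_start, dtype=np.int64),
            "end": np.asarray(out_end, dtype=np.int64),
        }
    )


def overlaps_any(query: pd.DataFrame, subject: pd.DataFrame) -> np.ndarray:
    """Boolean mask: does each query interval overlap (>=1 bp) any subject?

    Implemented by binary search against the merged, sorted subject set; the
    test suite checks it against a brute-force double loop.
    """
    result = np.zeros(len(query), dtype=bool)
    if len(query) == 0 or len(subject) == 0:
        return result
    merged = merge_intervals(subject)
    by_chrom = {c: s for c, s in merged.groupby("chrom", sort=False)}
    for chrom, sub in query.groupby("chrom", sort=False):
        if chrom not in by_chrom:
            continue
        ms = by_chrom[chrom]["start"].to_numpy()
        me = by_chrom[chrom]["end"].to_numpy()
        qs = sub["start"].to_numpy()
        qe = sub["end"].to_numpy()
        idx = np.searchsorted(ms, qe, side="left")
        hit = (idx > 0) & (me[np.maximum(idx - 1, 0)] > qs)
        result[sub.index.to_numpy()] = hit
    return result


def intersect_pair(a: pd.DataFrame, b: pd.DataFrame) -> pd.DataFrame:
    """Base-pair intersection of two interval sets (per chromosome sweep)."""
    pieces_chrom: list[str] = []
    pieces_start: list[int] = []
    pieces_end: list[int] = []
    a_by = {c: s for c, s in merge_intervals(a).groupby("chrom", sort=False)}
    b_by = {c: s for c, s in merge_intervals(b).groupby("chrom", sort=False)}
    for chrom in sorted(set(a_by) & set(b_by)):
        as_ = a_by[chrom]["start"].to_numpy()
        ae = a_by[chrom]["end"].to_numpy()
        bs = b_by[chrom]["start"].to_numpy()
        be = b_by[chrom]["end"].to_numpy()
        i = j = 0
        while i < len(as_) and j < len(bs):
            s = max(as_[i], bs[j])
            e = min(ae[i], be[j])
            if s < e:
                pieces_chrom.append(chrom)
                pieces_start.append(int(s))
                pieces_end.append(int(e))
            if ae[i] <= be[j]:
                i += 1
            else:
                j += 1
    return pd.DataFrame(
        {
            "chrom": pieces_chrom,
            "start": np.asarray(pieces_start, dtype=np.int64),
            "end": np.asarray(pieces_end, dtype=np.int64),
        }
    )
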