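"""Width-preserving randomised control distributions for an origin catalogue.

Two modes mirror the two reference distributions used to judge origin
spacing, timing and feature overlap against chance:

* ``chromosome`` — each origin keeps its chromosome and width, and its start
  is redrawn uniformly along the chromosome.  This destroys both clustering
  and any association with the replication-timing landscape.
* ``timing_jitter`` — each origin is shifted by a uniform offset within
  +/- ``jitter_halfwidth`` (default 240 kb, half the average width of an
  early replication-timing window).  This destroys fine-scale clustering
  while approximately preserving the timing profile.

Placements that would extend past the chromosome end are redrawn (up to
``max_redraws``); widths are preserved exactly, and null origins are allowed
to overlap each other.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .core import GenomeModel, stage_rng
from .catalog import OriginSet


@dataclass
class NullConfig:
    mode: str = "chromosome"  # or "timing_jitter"
    jitter_halfwidth: int = 240_000
    seed: int = 0
    max_redraws: int = 1000

    def __post_init__(self) -> None:
        if self.jitter_halfwidth <= 0:
            raise ValueError("jitter_halfwidth must be positive")
        if self.mode not in ("chromosome", "timing_jitter"):
            raise ValueError(f"unknown null mode {self.mode!r}")


def randomize(origins: OriginSet, genome: GenomeModel, cfg: NullConfig) -> OriginSet:
    if cfg.mode == "chromosome":
        return randomize_within_chromosome(origins, genome, cfg)
    return randomize_within_timing(origins, genome, cfg)


def randomize_within_chromosome(
    origins: OriginSet, genome: GenomeModel, cfg: NullConfig
) -> OriginSet:
    """Uniform redraw of each origin's start within its chromosome."""
    rng = stage_rng(cfg.seed, "null-chromosome")
    df = origins.df
    new_start = np.empty(len(df), dtype=np.int64)
    for i, row in enumerate(df.itertuples(index=False)):
        length = genome.chromosomes.get(row.chrom)
        if length is None:
            raise ValueError(f"origin on unknown chromosome {row.chrom!r}")
        width = row.end - row.start
        placed = False
        for _ in range(cfg.max_redraws):
            s = int(rng.integers(0, length))
            if s + width <= length:
                new_start[i] = s
                placed = True
                break
        if not placed:
            raise ValueError(
                f"could not place origin {row.chrom}:{row.start}-{row.end} "
                f"(width {width}) within {row.chrom} after {cfg.max_redraws} redraws"
            )
    out = df.copy()
    out["end"] = new_start + (df["end"] - df["start"]).to_numpy()
    out["start"] = new_start
    return OriginSet(out[["chrom", "start", "end"]],
                     {"null": "chromosome", "seed": cfg.seed})


def randomize_within_timing(
    origins: OriginSet, genome: GenomeModel, cfg: NullConfig
) -> OriginSet:
    """Shift each origin by a uniform offset in [-jitter, +jitter]."""
    rng = stage_rng(cfg.seed, "null-timing")
    df = origins.df
    J = cfg.jitter_halfwidth
    new_start = np.empty(len(df), dtype=np.int64)
    for i, row in enumerate(df.itertuples(index=False)):
        length = genome.chromosomes.get(row.chrom)
        if length is None:
            raise ValueError(f"origin on unknown chromosome {row.chrom!r}")
        width = row.end - row.start
        lo, hi = max(0, row.start - J), min(length - width, row.start + J)
        if lo > hi:
            raise ValueError(
                f"origin {row.chrom}:{row.start}-{row.end} cannot be jittered "
                f"within the chromosome"
            )
        placed = False
        for _ in range(cfg.max_redraws):
            s = row.start + int(rng.integers(-J, J + 1))
            if 0 <= s and s + width <= length:
                new_start[i] = s
                placed = True
                break
        if not placed:
            raise ValueError(
                f"could not jitter origin {row.chrom}:{row.start}-{row.end} "
                f"after {cfg.max_redraws} redraws"
            )
    out = df.copy()
    out["end"] = new_start + (df["end"] - df["start"]).to_numpy()
    out["start"] = new_start
    return OriginSet(out[["chrom", "start", "end"]],
                     {"null": "timing_jitter", "jitter": J, "seed": cfg.seed})
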