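"""Sequence-level features: G-quadruplex motif scanning and compositional skew.

The G4 motif is ``n_runs`` blocks of at least ``min_run`` consecutive
guanines separated by loops of ``loop_min``–``loop_max`` bases (quadparser
convention: loops 1–7 bp, runs of >= 3 G).  Scanning is leftmost and
non-re-entrant: the first match wins and scanning resumes after it.  G-runs
are matched greedily and loops lazily, so reported motifs use the shortest
loops consistent with a match.  ``N`` bases never participate in a motif.

The compositional skew per window is

    S = (T - A)/(T + A) + (G - C)/(G + C)

computed on the + strand; a term whose denominator is zero contributes 0,
so S is always in [-2, 2] and an all-T window scores exactly 1.
"""

from __future__ import annotations

import re
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core import FeatureTrack

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass
class G4Params:
    min_run: int = 3
    n_runs: int = 4
    loop_min: int = 1
    loop_max: int = 7
    scan_both_strands: bool = True

    def __post_init__(self) -> None:
        if self.min_run < 2 or self.n_runs < 2:
            raise ValueError("min_run and n_runs must each be >= 2")
        if not 0 <= self.loop_min <= self.loop_max:
            raise ValueError("require 0 <= loop_min <= loop_max")

    def pattern(self, base: str) -> re.Pattern:
        run = f"{base}{{{self.min_run},}}"
        loop = f"[ACGT]{{{self.loop_min},{self.loop_max}}}?"  # lazy: shortest loop
        return re.compile(run + f"(?:{loop}{run}){{{self.n_runs - 1}}}")


def scan_g4(sequence: str, params: G4Params | None = None,
            chrom: str = "seq") -> FeatureTrack:
    """Scan one sequence for G4 motifs on the + strand (G-runs) and, if
    ``scan_both_strands``, the - strand (C-run pattern reported at the same
    + coordinates with strand ``-``)."""
    params = params or G4Params()
    seq = sequence.upper()
    rows: list[tuple] = []
    strands = [("G", "+")] + ([("C", "-")] if params.scan_both_strands else [])
    for base, strand in strands:
        pat = params.pattern(base)
        for i, m in enumerate(pat.finditer(seq)):
            rows.append((chrom, m.start(), m.end(), f"g4_{strand}_{i}", strand))
    df = pd.DataFrame(rows, columns=["chrom", "start", "end", "name", "strand"])
    return FeatureTrack("g4", df.sort_values(["start", "end"]).reset_index(drop=True))


def scan_g4_genome(sequences: dict[str, str],
                   params: G4Params | None = None) -> FeatureTrack:
    parts = [scan_g4(seq, params, chrom=name).df for name, seq in sequences.items()]
    df = pd.concat(parts, ignore_index=True) if parts else None
    return FeatureTrack("g4", df)


@dataclass
class SkewProfile:
    window: int
    values: np.ndarray          # S per window, anchored at coordinate 0
    last_window_partial: bool   # trailing window computed on < window bases

    @property
    def starts(self) -> np.ndarray:
        return np.arange(len(self.values), dtype=np.int64) * self.window


def _skew_terms(t: np.ndarray, a: np.ndarray, g: np.ndarray, c: np.ndarray) -> np.ndarray:
    with np.errstate(divide="ignore", invalid="ignore"):
        ta = np.where(t + a > 0, (t - a) / np.maximum(t + a, 1), 0.0)
        gc = np.where(g + c > 0, (g - c) / np.maximum(g + c, 1), 0.0)
    return ta + gc


def skew_profile(sequence: str, window: int = 1_000) -> SkewProfile:
    """Per-window compositional skew S on the + strand.

    Windows are non-overlapping and anchored at 0; a trailing partial window
    is computed over its remaining bases and flagged.
    """
    if window <= 0:
        raise ValueError("window must be positive")
    seq = np.frombuffer(sequence.upper().encode("ascii"), dtype=np.uint8)
    n = len(seq)
    if n == 0:
        return SkewProfile(window, np.zeros(0), False)
    n_win = -(-n // window)
    idx = np.arange(n) // window
    counts = {}
    for letter in "ACGT":
        counts[letter] = np.bincount(idx[seq == ord(letter)], minlength=n_win).astype(float)
    values = _skew_terms(counts["T"], counts["A"], counts["G"], counts["C"])
    return SkewProfile(window, values, bool(n % window))
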