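"""Independent brute-force oracles used to check the package's fast paths.

Everything here is deliberately naive: O(n*m) double loops, exhaustive
enumeration and direct recursive matching, sharing no code with the
implementations under test.
"""

from __future__ import annotations

import math

import numpy as np
import pandas as pd
from scipy.stats import poisson


# ---------------------------------------------------------------------------
# Interval arithmetic
# ---------------------------------------------------------------------------

def brute_overlaps_any(query: pd.DataFrame, subject: pd.DataFrame) -> np.ndarray:
    out = np.zeros(len(query), dtype=bool)
    subj = list(subject.itertuples(index=False))
    for i, q in enumerate(query.itertuples(index=False)):
        for s in subj:
            if s.chrom == q.chrom and q.start < s.end and s.start < q.end:
                out[i] = True
                break
    return out


def brute_intersect(a: pd.DataFrame, b: pd.DataFrame) -> list[tuple[str, int, int]]:
    """All pairwise base-pair intersections, unioned and merged."""
    pieces = []
    for x in a.itertuples(index=False):
        for y in b.itertuples(index=False):
            if x.chrom != y.chrom:
                continue
            s, e = max(x.start, y.start), min(x.end, y.end)
            if s < e:
                pieces.append((x.chrom, int(s), int(e)))
    # merge overlapping/book-ended pieces
    pieces.sort()
    merged: list[tuple[str, int, int]] = []
    for chrom, s, e in pieces:
        if merged and merged[-1][0] == chrom and s <= merged[-1][2]:
            prev = merged.pop()
            merged.append((chrom, prev[1], max(prev[2], e)))
        else:
            merged.append((chrom, s, e))
    return merged


# ---------------------------------------------------------------------------
# Island caller
# ---------------------------------------------------------------------------

def eligibility_by_tail_scan(lam: float, p: float, k_cap: int = 10_000) -> int:
    """Smallest l0 with P(X >= l0) < p, by explicit tail summation."""
    for k in range(k_cap):
        tail = 1.0 - sum(
            math.exp(-lam) * lam**j / math.factorial(j) for j in range(k)
        )
        if tail < p:
            return k
    raise RuntimeError("no eligibility threshold found")


def linear_scan_islands(
    counts: np.ndarray, lam: float, l0: int, gap: int, window: int,
    chrom_len: int | None = None,
) -> list[tuple[int, int, float, int]]:
    """Independent scan for maximal eligible-window runs with gaps <= gap.

    Returns (start_bp, end_bp, score, tag_count) tuples.  Written as a plain
    left-to-right state machine, unlike the vectorised implementation.
    """
    chrom_len = chrom_len if chrom_len is not None else len(counts) * window
    islands = []
    i = 0
    n = len(counts)
    while i < n:
        if counts[i] < l0:
            i += 1
            continue
        start = i
        last_elig = i
        j = i + 1
        while j < n:
            if counts[j] >= l0:
                last_elig = j
                j += 1
            elif j - last_elig <= gap:
                j += 1
            else:
                break
        score = sum(
            float(-poisson.logpmf(int(counts[k]), lam))
            for k in range(start, last_elig + 1)
            if counts[k] >= l0
        )
        tag_count = int(counts[start : last_elig + 1].sum())
        islands.append(
            (start * window, min((last_elig + 1) * window, chrom_len), score, tag_count)
        )
        i = last_elig + 1
    return islands


def exhaustive_island_candidates(
    counts: np.ndarray, lam: float, l0: int, gap: int
) -> list[tuple[int, int, float]]:
    """Every maximal valid window run, found by checking all (i, j) pairs.

    A run [i, j] is a candidate iff windows i and j are eligible, no internal
    stretch of > gap consecutive ineligible windows exists, and the run
    cannot be extended on either side.  Returns (i, j, score).
    """
    n = len(counts)
    elig = [c >= l0 for c in counts]

    # valid[i][j]: is [i, j] a candidate run?  Built by extending j for each i.
    valid = [[False] * n for _ in range(n)]
    for i in range(n):
        if not elig[i]:
            continue
        bad_run = 0
        for j in range(i, n):
            if elig[j]:
                bad_run = 0
                valid[i][j] = True
            else:
                bad_run += 1
                if bad_run > gap:
                    break

    def extendable(i: int, j: int) -> bool:
        return any(valid[i2][j] for i2 in range(i)) or any(
            valid[i][j2] for j2 in range(j + 1, n)
        )

    out = []
    for i in range(n):
        for j in range(i, n):
            if valid[i][j] and not extendable(i, j):
                score = sum(
                    float(-poisson.logpmf(int(counts[k]), lam))
                    for k in range(i, j + 1)
                    if elig[k]
                )
                out.append((i, j, score))
    return out


# ---------------------------------------------------------------------------
# G4 motif matching
# ---------------------------------------------------------------------------

def g4_matches(seq: str, base: str = "G", min_run: int = 3, n_runs: int = 4,
               loop_min: int = 1, loop_max: int = 7) -> list[tuple[int, int]]:
    """Leftmost, non-re-entrant G4 matches by explicit recursive backtracking.

    Token semantics: runs are greedy (longest first), loops lazy (shortest
    first); N never matches anywhere.  Mirrors the documented scanner
    contract without using the re module.
    """
    seq = seq.upper()
    n = len(seq)
    loop_alphabet = set("ACGT")

    def match_run(pos: int):
        """Yield end positions for a greedy run of >= min_run `base`."""
        end = pos
        while end < n and seq[end] == base:
            end += 1
        yield from range(end, pos + min_run - 1, -1)  # longest first

    def match_from(pos: int, runs_left: int):
        """Yield match ends in backtracking-priority order (innermost fastest)."""
        for run_end in match_run(pos):
            if runs_left == 1:
                yield run_end
                continue
            for loop_len in range(loop_min, loop_max + 1):  # lazy loop
                loop_end = run_end + loop_len
                if loop_end > n:
                    break
                if any(c not in loop_alphabet for c in seq[run_end:loop_end]):
                    break
                yield from match_from(loop_end, runs_left - 1)

    out = []
    pos = 0
    while pos < n:
        matched = None
        for end in match_from(pos, n_runs):
            matched = end
            break
        if matched is not None:
            out.append((pos, matched))
            pos = matched
        else:
            pos += 1
    return out


# ---------------------------------------------------------------------------
# Skew
# ---------------------------------------------------------------------------

def skew_by_counting(window_seq: str) -> float:
    t = window_seq.count("T")
    a = window_seq.count("A")
    g = window_seq.count("G")
    c = window_seq.count("C")
    ta = (t - a) / (t + a) if (t + a) else 0.0
    gc = (g - c) / (g + c) if (g + c) else 0.0
    return ta + gc
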