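"""SICER-style broad-enrichment island calling.

The genome is partitioned into fixed, non-overlapping windows anchored at
coordinate 0 of every chromosome.  Read tags, shifted to their estimated
fragment midpoints, are counted per window against a uniform Poisson
background with rate

    lambda = total_tags * window_size / (effective_genome_fraction * genome_length).

Windows with a count whose upper Poisson tail falls below ``eligibility_p``
are *eligible*; maximal runs of eligible windows (allowing up to ``gap_size``
ineligible windows inside) form candidate islands.  An island's score is the
sum over its eligible windows of -ln P(count; lambda).  Candidates are kept
in one of two modes:

* **no-input (E-value) mode** — keep islands whose score meets a threshold
  calibrated so that the expected number of background islands at or above
  it, genome-wide, does not exceed ``e_value``.  The null island-score
  distribution is computed either exactly by dynamic programming over
  eligible-window score contributions (``null_method="recursion"``) or by
  Monte-Carlo simulation of Poisson window counts.
* **with-input (FDR) mode** — score each candidate's tag count against the
  input library count over the same span (scaled by library sizes, floored
  at a pseudocount of 1) with an upper Poisson tail, then Benjamini–Hochberg
  across candidates at ``fdr``.

Adjacent called islands separated by at most one window are merged in a
separate post-processing step (:func:`merge_adjacent`).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import poisson
from statsmodels.stats.multitest import multipletests

from .core import GenomeModel, ReadLibrary, stage_rng

ISLAND_COLUMNS = ["chrom", "start", "end", "score", "tag_count"]


@dataclass
class CallerConfig:
    window_size: int = 150
    gap_size: int = 0          # in windows
    fragment_size: int = 200
    effective_genome_fraction: float = 0.793
    redundancy_threshold: int = 1
    e_value: float = 1e-5
    fdr: float = 1e-5
    eligibility_p: float = 0.2
    null_method: str = "recursion"  # or "monte_carlo"
    mc_replicates: int = 500
    seed: int = 0

    def __post_init__(self) -> None:
        if self.window_size <= 0:
            raise ValueError("window_size must be positive")
        if self.gap_size < 0:
            raise ValueError("gap_size must be >= 0")
        if not 0 < self.effective_genome_fraction <= 1:
            raise ValueError("effective_genome_fraction must be in (0, 1]")
        if self.e_value <= 0:
            raise ValueError("e_value must be positive")
        if not 0 < self.fdr < 1:
            raise ValueError("fdr must be in (0, 1)")
        if self.null_method not in ("recursion", "monte_carlo"):
            raise ValueError(f"unknown null_method {self.null_method!r}")


@dataclass
class WindowCounts:
    """Per-chromosome window tag counts plus the Poisson background rate."""

    counts: dict[str, np.ndarray]
    window_size: int
    total_tags: int
    effective_length: float
    chrom_lengths: dict[str, int] = field(default_factory=dict)

    @property
    def lam(self) -> float:
        """Expected background tags per window."""
        if self.effective_length <= 0:
            return 0.0
        return self.total_tags * self.window_size / self.effective_length

    @property
    def n_windows(self) -> int:
        return int(sum(len(v) for v in self.counts.values()))


def bin_reads(lib: ReadLibrary, genome: GenomeModel, cfg: CallerConfig) -> WindowCounts:
    """Count fragment-midpoint-shifted tags in fixed windows.

    A ``+`` tag contributes at ``start + fragment_size//2``, a ``-`` tag at
    ``end - fragment_size//2`` (un-stranded tags are treated as ``+``);
    midpoints are clipped into the chromosome so every tag is counted.
    """
    w = cfg.window_size
    counts: dict[str, np.ndarray] = {}
    for chrom, length in genome.chromosomes.items():
        n_win = max(1, -(-length // w))  # ceil; trailing partial window kept
        counts[chrom] = np.zeros(n_win, dtype=np.int64)
    for chrom, sub in lib.df.groupby("chrom", sort=False):
        if chrom not in counts:
            continue
        length = genome.chromosomes[chrom]
        minus = (sub["strand"] == "-").to_numpy()
        mid = np.where(
            minus,
            sub["end"].to_numpy() - cfg.fragment_size // 2,
            sub["start"].to_numpy() + cfg.fragment_size // 2,
        )
        mid = np.clip(mid, 0, length - 1)
        win = mid // w
        counts[chrom] += np.bincount(win, minlength=len(counts[chrom]))
    return WindowCounts(
        counts=counts,
        window_size=w,
        total_tags=lib.total_tags,
        effective_length=cfg.effective_genome_fraction * genome.total_length,
        chrom_lengths=dict(genome.chromosomes),
    )


def eligibility_threshold(lam: float, eligibility_p: float) -> int:
    """Smallest count l0 with upper Poisson tail P(X >= l0; lam) < eligibility_p."""
    if lam <= 0:
        raise ValueError("lam must be positive")
    if eligibility_p >= 1:
        return 0
    # P(X >= k) = sf(k - 1); isf gives a starting guess, then adjust
    k = max(int(poisson.isf(eligibility_p, lam)), 0)
    while poisson.sf(k - 1, lam) >= eligibility_p:
        k += 1
    while k > 0 and poisson.sf(k - 2, lam) < eligibility_p:
        k -= 1
    return k


def _window_scores(counts: np.ndarray, lam: float) -> np.ndarray:
    with np.errstate(divide="ignore"):
        return -poisson.logpmf(counts, lam)


def find_islands(counts: WindowCounts, cfg: CallerConfig) -> pd.DataFrame:
    """Candidate islands: maximal runs of eligible windows with gaps <= gap_size.

    Islands start and end on eligible windows.  The score sums the per-window
    -ln Poisson probabilities of the *eligible* member windows; tag_count sums
    every window in the island span (gap windows included).
    """
    lam = counts.lam
    rows: list[tuple] = []
    if lam <= 0:
        return pd.DataFrame(columns=ISLAND_COLUMNS)
    l0 = eligibility_threshold(lam, cfg.eligibility_p)
    w = counts.window_size
    for chrom, vec in counts.counts.items():
        elig = np.flatnonzero(vec >= l0) if l0 > 0 else np.arange(len(vec))
        if len(elig) == 0:
            continue
        breaks = np.flatnonzero(np.diff(elig) > cfg.gap_size + 1)
        starts = np.r_[0, breaks + 1]
        ends = np.r_[breaks, len(elig) - 1]
        chrom_len = counts.chrom_lengths.get(chrom, len(vec) * w)
        scores_all = _window_scores(vec, lam)
        for a, b in zip(starts, ends):
            members = elig[a : b + 1]
            w0, w1 = int(elig[a]), int(elig[b])
            score = float(scores_all[members].sum())
            tag_count = int(vec[w0 : w1 + 1].sum())
            rows.append((chrom, w0 * w, min((w1 + 1) * w, chrom_len), score, tag_count))
    return pd.DataFrame(rows, columns=ISLAND_COLUMNS)


# ---------------------------------------------------------------------------
# E-value calibration of the island score threshold
# ---------------------------------------------------------------------------

_SCORE_BIN = 0.01


def _single_window_score_dist(lam: float, l0: int) -> tuple[np.ndarray, float]:
    """Unnormalised score distribution of one eligible window, on a grid.

    Returns (weights over score grid with bin _SCORE_BIN, total eligible
    probability q).  Counts with negligible probability (< 1e-15) are cut.
    """
    k_max = max(l0, int(poisson.isf(1e-14, lam))) + 2
    ks = np.arange(max(l0, 0), k_max + 1)
    pk = poisson.pmf(ks, lam)
    keep = pk > 1e-300
    ks, pk = ks[keep], pk[keep]
    if len(ks) == 0:
        return np.zeros(1), 0.0
    scores = -poisson.logpmf(ks, lam)
    bins = np.round(scores / _SCORE_BIN).astype(int)
    weights = np.zeros(int(bins.max()) + 1)
    np.add.at(weights, bins, pk)
    return weights, float(pk.sum())


def expected_islands_curve(lam: float, n_windows: int, eligibility_p: float
                           ) -> tuple[np.ndarray, np.ndarray]:
    """Expected number of background islands with score >= s, for gap 0.

    Dynamic programming over island lengths: a run of exactly m eligible
    windows starting at a given position has probability
    (1-q)^2 * conv_m(score), where conv_m is the m-fold convolution of the
    single-eligible-window score distribution.  Returns (score_grid, E(s)).
    """
    l0 = eligibility_threshold(lam, eligibility_p)
    if l0 == 0:
        # every window eligible: one island per chromosome regardless of score
        raise ValueError("eligibility_p >= 1 leaves no background model to calibrate")
    w1, q = _single_window_score_dist(lam, l0)
    if q <= 0:
        return np.array([0.0]), np.array([0.0])
    # truncate island length when residual run probability is negligible
    tiny = 1e-12 / max(n_windows, 1)
    m_max = max(1, int(np.ceil(np.log(tiny) / np.log(q))))
    density = np.zeros(len(w1) * m_max + 1)
    conv = w1.copy()
    for _ in range(m_max):
        density[: len(conv)] += conv
        if conv.sum() < tiny:
            break
        conv = np.convolve(conv, w1)
    density *= (1.0 - q) ** 2 * n_windows
    grid = np.arange(len(density)) * _SCORE_BIN
    tail = np.cumsum(density[::-1])[::-1]
    return grid, tail


def calibrate_score_threshold(
    cfg: CallerConfig, lam: float, n_windows: int
) -> float:
    """Smallest score s* with expected background islands (score >= s*) <= e_value."""
    if lam <= 0 or n_windows <= 0:
        raise ValueError("lam and n_windows must be positive")
    if not np.isfinite(cfg.e_value):
        return 0.0
    l0 = eligibility_threshold(lam, cfg.eligibility_p)
    if l0 > 0 and poisson.sf(l0 - 1, lam) <= 0:
        return 0.0  # no window can ever be eligible: empty null
    if cfg.null_method == "monte_carlo":
        return _calibrate_monte_carlo(cfg, lam, n_windows)
    grid, tail = expected_islands_curve(lam, n_windows, cfg.eligibility_p)
    if tail[0] <= cfg.e_value:
        warnings.warn("e_value exceeds total expected background islands; threshold 0")
        return 0.0
    idx = np.searchsorted(-tail, -cfg.e_value, side="left")
    return float(grid[min(idx, len(grid) - 1)])


def _calibrate_monte_carlo(cfg: CallerConfig, lam: float, n_windows: int) -> float:
    rng = stage_rng(cfg.seed, "caller-mc")
    all_scores: list[np.ndarray] = []
    for _ in range(cfg.mc_replicates):
        vec = rng.poisson(lam, size=n_windows)
        # score against the analytic lambda, not the per-replicate empirical one
        all_scores.append(_find_islands_at_lambda(vec, lam, cfg))
    pooled = np.sort(np.concatenate(all_scores))[::-1]
    if len(pooled) == 0:
        return 0.0
    # smallest s with (mean islands scoring >= s per replicate) <= e_value
    allowed = int(np.floor(cfg.e_value * cfg.mc_replicates))
    if allowed >= len(pooled):
        warnings.warn("e_value exceeds observed background islands; threshold 0")
        return 0.0
    return float(pooled[allowed]) + _SCORE_BIN


def _find_islands_at_lambda(vec: np.ndarray, lam: float, cfg: CallerConfig) -> np.ndarray:
    """Scores of islands in a single count vector under a fixed lambda."""
    l0 = eligibility_threshold(lam, cfg.eligibility_p)
    elig = np.flatnonzero(vec >= l0) if l0 > 0 else np.arange(len(vec))
    if len(elig) == 0:
        return np.empty(0)
    breaks = np.flatnonzero(np.diff(elig) > cfg.gap_size + 1)
    starts = np.r_[0, breaks + 1]
    ends = np.r_[breaks, len(elig) - 1]
    scores_all = _window_scores(vec, lam)
    out = np.empty(len(starts))
    for i, (a, b) in enumerate(zip(starts, ends)):
        members = elig[a : b + 1]
        out[i] = scores_all[members].sum()
    return out


# ---------------------------------------------------------------------------
# Calling modes
# ---------------------------------------------------------------------------

def call_islands_no_input(
    lib: ReadLibrary,
    genome: GenomeModel,
    cfg: CallerConfig,
    score_threshold: float | None = None,
) -> pd.DataFrame:
    """E-value mode: candidate islands filtered at the calibrated score threshold.

    ``score_threshold`` may be supplied to reuse a previously calibrated
    value (the threshold depends only on lambda, the window count and the
    config).  Islands scoring exactly at the threshold are retained.
    """
    if lib.total_tags == 0:
        return pd.DataFrame(columns=ISLAND_COLUMNS)
    counts = bin_reads(lib, genome, cfg)
    candidates = find_islands(counts, cfg)
    if score_threshold is None:
        score_threshold = calibrate_score_threshold(cfg, counts.lam, counts.n_windows)
    return candidates[candidates["score"] >= score_threshold].reset_index(drop=True)


def call_islands_with_input(
    lib: ReadLibrary,
    input_lib: ReadLibrary,
    genome: GenomeModel,
    cfg: CallerConfig,
) -> pd.DataFrame:
    """FDR mode: candidate islands tested against the scaled input library.

    Each candidate's significance is the upper Poisson tail of its IP tag
    count with mean = (input tags in span, floored at 1) * (IP size / input
    size); Benjamini–Hochberg q-values are thresholded at ``cfg.fdr``.
    """
    if input_lib.total_tags == 0:
        raise ValueError("with-input mode requires a non-empty input library")
    if lib.total_tags == 0:
        return pd.DataFrame(columns=ISLAND_COLUMNS + ["significance"])
    ip_counts = bin_reads(lib, genome, cfg)
    in_counts = bin_reads(input_lib, genome, cfg)
    candidates = find_islands(ip_counts, cfg)
    if len(candidates) == 0:
        return candidates.assign(significance=pd.Series(dtype=float))
    scale = lib.total_tags / input_lib.total_tags
    w = cfg.window_size
    pvals = np.empty(len(candidates))
    for i, row in enumerate(candidates.itertuples(index=False)):
        vec = in_counts.counts[row.chrom]
        w0 = row.start // w
        w1 = min((row.end - 1) // w, len(vec) - 1)
        input_count = max(int(vec[w0 : w1 + 1].sum()), 1)
        pvals[i] = poisson.sf(row.tag_count - 1, input_count * scale)
    _, qvals, _, _ = multipletests(pvals, method="fdr_bh")
    out = candidates.assign(significance=qvals)
    return out[out["significance"] <= cfg.fdr].reset_index(drop=True)


def merge_adjacent(islands: pd.DataFrame, cfg: CallerConfig) -> pd.DataFrame:
    """Merge same-chromosome islands separated by at most one window.

    Scores and tag counts of merged islands are summed.  Idempotent: the gap
    after a merge is necessarily larger than one window.
    """
    if len(islands) == 0:
        return islands.copy()
    has_sig = "significance" in islands.columns
    rows = []
    for chrom, sub in islands.sort_values(["chrom", "start"]).groupby("chrom", sort=True):
        sub = sub.reset_index(drop=True)
        cur = sub.iloc[0].to_dict()
        for _, row in sub.iloc[1:].iterrows():
            if row["start"] - cur["end"] <= cfg.window_size:
                cur["end"] = max(cur["end"], row["end"])
                cur["score"] += row["score"]
                cur["tag_count"] += row["tag_count"]
                if has_sig:
                    cur["significance"] = min(cur["significance"], row["significance"])
            else:
                rows.append(cur)
                cur = row.to_dict()
        rows.append(cur)
    cols = ISLAND_COLUMNS + (["significance"] if has_sig else [])
    return pd.DataFrame(rows)[cols].reset_index(drop=True)
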