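"""Synthetic genome, planted origins and read libraries.

The generator emulates the statistical structure of a cell-free nascent-DNA
labelling experiment: per simulated nucleus, each planted origin fires with
its own probability after a uniform lag of up to ``max_lag`` minutes, and two
labelled tracts extend bidirectionally at independently drawn fork rates
(normal, mean 300 sd 200 bp/min, truncated at 1) for the remainder of a
15-minute labelling window.  Immunoprecipitated fragments are sampled
uniformly along the labelled tracts with sonication-like lengths (uniform
100–1000 bp); a small fraction of fragments (default 3.5%, the contaminating
S-phase elongation background) and the whole input library are placed
uniformly genome-wide.  Replicate libraries A and B differ only in their
immunoprecipitation efficiency, so A can be given half the per-origin depth
of B.

The toy genome carries the feature landscape the downstream analytics need:
genes with TSS/exons/introns, a repeating tiled S1–S6 replication-timing
landscape with overlapping domain edges, sparse excluded regions, planted G4
motifs written into the sequence at a subset of TSS, and positive skew jumps
at "germline" origins (plus decoy negative jumps far from any origin).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.stats import truncnorm

from .core import FeatureTrack, GenomeModel, ReadLibrary, stage_rng
from .overlap import TIMING_CLASSES

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


@dataclass
class SimConfig:
    n_chromosomes: int = 2
    chrom_length: int = 5_760_000   # two full S1..S6 timing cycles of 480 kb
    n_genes: int = 600
    n_origins: int = 200
    frac_origins_at_tss: float = 0.5
    frac_origins_early: float = 0.75
    frac_origins_clustered: float = 0.2
    frac_origins_germline: float = 0.15
    firing_probability: float = 0.3
    n_nuclei: int = 100
    fork_rate_mean: float = 300.0   # bp/min
    fork_rate_sd: float = 200.0
    labelling_time: float = 15.0    # min
    max_lag: float = 10.0           # min
    s_phase_background_fraction: float = 0.035
    fragment_min: int = 100
    fragment_max: int = 1000
    ip_efficiency_A: float = 0.5
    ip_efficiency_B: float = 1.0
    reads_input: int = 100_000
    timing_domain_bp: int = 480_000
    timing_overlap_bp: int = 60_000
    tss_halfwidth: int = 500
    frac_tss_with_g4: float = 0.6
    n_negative_jumps: int = 30
    gc_content: float = 0.41
    seed: int = 0

    def __post_init__(self) -> None:
        for name in (
            "frac_origins_at_tss", "frac_origins_early", "frac_origins_clustered",
            "frac_origins_germline", "firing_probability",
            "s_phase_background_fraction", "frac_tss_with_g4",
        ):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if self.fragment_min > self.fragment_max or self.fragment_min <= 0:
            raise ValueError("require 0 < fragment_min <= fragment_max")
        if self.labelling_time <= 0:
            raise ValueError("labelling_time must be positive")
        if self.max_lag < 0 or self.max_lag > self.labelling_time:
            raise ValueError("require 0 <= max_lag <= labelling_time")
        if self.n_chromosomes <= 0 or self.chrom_length <= 0:
            raise ValueError("need at least one chromosome of positive length")

    @property
    def mean_fragment_length(self) -> float:
        return (self.fragment_min + self.fragment_max) / 2.0


@dataclass
class SimulationTruth:
    """Planted ground truth: origin table and skew-jump table."""

    origins: pd.DataFrame  # chrom, position, firing_probability, timing_class,
                           # at_tss, has_g4, germline
    jumps: pd.DataFrame    # chrom, position, polarity

    def __len__(self) -> int:
        return len(self.origins)


# ---------------------------------------------------------------------------
# Genome generation
# ---------------------------------------------------------------------------

def _random_sequence(rng: np.random.Generator, length: int, gc: float) -> np.ndarray:
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    return rng.choice(_BASES, size=length, p=p)


def _make_g4_motif(rng: np.random.Generator) -> str:
    """Canonical planted motif G3 N3 G3 N3 G3 N3 G3 with G-free loops."""
    loops = ["".join(rng.choice(list("ACT"), size=3)) for _ in range(3)]
    return "GGG" + "GGG".join(loops) + "GGG"


def generate_genome(config: SimConfig) -> GenomeModel:
    """Build the toy genome: sequences plus gene/TSS/exon/timing/excluded/G4 tracks.

    Deterministic for a fixed seed; timing domains tile every chromosome with
    a repeating S1->S6 cycle whose domains overlap their neighbours by
    ``timing_overlap_bp`` on each side.
    """
    rng = stage_rng(config.seed, "genome")
    chroms = {f"chr{i + 1}": config.chrom_length for i in range(config.n_chromosomes)}
    sequences: dict[str, np.ndarray] = {
        name: _random_sequence(rng, length, config.gc_content)
        for name, length in chroms.items()
    }

    genes, tss, exons = [], [], []
    per_chrom = np.full(config.n_chromosomes, config.n_genes // config.n_chromosomes)
    per_chrom[: config.n_genes % config.n_chromosomes] += 1
    for ci, (chrom, length) in enumerate(chroms.items()):
        n = int(per_chrom[ci])
        if n == 0:
            continue
        # one gene per equal slot guarantees non-overlap; gene lengths adapt
        # to the slot so dense configurations remain valid
        slot = length // n
        gmax = min(20_000, slot - 2_000)
        if gmax < 1_000:
            raise ValueError(
                f"chromosome {chrom} too short to host {n} genes "
                f"({slot} bp per gene)"
            )
        gmin = min(4_000, max(gmax // 2, 500))
        for gi in range(n):
            glen = int(rng.integers(gmin, gmax + 1))
            offset = int(rng.integers(1_000, slot - glen - 1_000 + 1))
            gstart = gi * slot + offset
            gend = gstart + glen
            strand = "+" if rng.random() < 0.5 else "-"
            name = f"{chrom}_gene{gi}"
            genes.append((chrom, gstart, gend, name, strand))
            t = gstart if strand == "+" else gend - 1
            tss.append((chrom, t, t + 1, name, strand))
            # exon structure: 1-4 exons walked from the 5' end of the span
            n_ex = int(rng.integers(1, 5))
            pos = gstart
            for ei in range(n_ex):
                elen = int(rng.integers(200, 1_001))
                if pos + elen > gend:
                    break
                exons.append((chrom, pos, pos + elen, f"{name}_ex{ei}", strand))
                pos += elen + int(rng.integers(500, 3_001))

    timing = []
    domain, ov = config.timing_domain_bp, config.timing_overlap_bp
    for chrom, length in chroms.items():
        k = 0
        pos = 0
        while pos < length:
            cls = TIMING_CLASSES[k % len(TIMING_CLASSES)]
            start = max(0, pos - ov)
            end = min(length, pos + domain + ov)
            timing.append((chrom, start, end, cls, "."))
            pos += domain
            k += 1

    # sparse excluded regions in intergenic space (between gene slots)
    excluded = []
    gene_df = pd.DataFrame(genes, columns=["chrom", "start", "end", "name", "strand"])
    for chrom, length in chroms.items():
        for _ in range(2):
            for _attempt in range(100):
                s = int(rng.integers(0, max(length - 10_000, 1)))
                e = s + 10_000
                sub = gene_df[gene_df["chrom"] == chrom]
                if not ((sub["start"] < e + 2_000) & (sub["end"] > s - 2_000)).any():
                    excluded.append((chrom, s, e, "excluded", "."))
                    break

    # plant G4 motifs near a subset of TSS, plus a few intergenic decoys
    g4 = []
    tss_df = pd.DataFrame(tss, columns=["chrom", "start", "end", "name", "strand"])
    for row in tss_df.itertuples(index=False):
        if rng.random() >= config.frac_tss_with_g4:
            continue
        motif = _make_g4_motif(rng)
        offset = int(rng.integers(-300, 301))
        s = max(1, min(row.start + offset, chroms[row.chrom] - len(motif) - 1))
        seq = sequences[row.chrom]
        seq[s : s + len(motif)] = np.frombuffer(motif.encode(), dtype=np.uint8)
        seq[s - 1] = ord("T")                 # guard bases: keep runs bounded
        seq[s + len(motif)] = ord("T")
        g4.append((row.chrom, s, s + len(motif), f"g4_{row.name}", "+"))
    for chrom, length in chroms.items():
        for di in range(10):
            motif = _make_g4_motif(rng)
            s = int(rng.integers(1, length - len(motif) - 1))
            seq = sequences[chrom]
            seq[s : s + len(motif)] = np.frombuffer(motif.encode(), dtype=np.uint8)
            seq[s - 1] = ord("T")
            seq[s + len(motif)] = ord("T")
            g4.append((chrom, s, s + len(motif), f"g4_{chrom}_ig{di}", "+"))

    genome = GenomeModel(
        chromosomes=chroms,
        sequences={name: arr.tobytes().decode("ascii") for name, arr in sequences.items()},
    )
    cols = ["chrom", "start", "end", "name", "strand"]
    genome.add_track(FeatureTrack("genes", gene_df))
    genome.add_track(FeatureTrack("tss", tss_df))
    genome.add_track(FeatureTrack("exons", pd.DataFrame(exons, columns=cols)))
    genome.add_track(FeatureTrack("timing", pd.DataFrame(timing, columns=cols)))
    genome.add_track(FeatureTrack("excluded", pd.DataFrame(excluded, columns=cols)))
    genome.add_track(FeatureTrack("g4", pd.DataFrame(g4, columns=cols)))
    return genome


# ---------------------------------------------------------------------------
# Origin planting
# ---------------------------------------------------------------------------

# conditional class weights: early origins favour S1 over S2, later origins
# thin out towards S6, giving the decreasing timing profile seen in real
# early-S catalogues
_EARLY_WEIGHTS = {"S1": 0.6, "S2": 0.4}
_LATE_WEIGHTS = {"S3": 0.4, "S4": 0.3, "S5": 0.2, "S6": 0.1}


def _timing_cores(genome: GenomeModel, overlap: int) -> dict[str, list[tuple[str, int, int]]]:
    """Per-class domain cores, trimmed so cores are class-pure.

    Stored domains already extend ``overlap`` bp past their tile on each
    side, and the neighbouring domain extends ``overlap`` bp in, so the
    class-pure stretch starts 2x overlap inside the stored bounds.
    """
    cores: dict[str, list[tuple[str, int, int]]] = {c: [] for c in TIMING_CLASSES}
    for row in genome.tracks["timing"].df.itertuples(index=False):
        s = row.start + 2 * overlap
        e = row.end - 2 * overlap
        if e > s:
            cores[row.name].append((row.chrom, int(s), int(e)))
    return cores


def plant_origins(genome: GenomeModel, config: SimConfig) -> SimulationTruth:
    """Place origins honouring the configured TSS and early-timing fractions.

    Per origin, Bernoulli draws decide TSS association and early (S1/S2)
    timing; a clustered subset is re-placed 1-5 kb from a partner origin of
    the same class, and a germline subset emits a positive skew jump at its
    position.  Raises if a class runs out of placement sites.
    """
    if "genes" not in genome.tracks or "timing" not in genome.tracks:
        raise ValueError("genome must provide gene and timing tracks")
    rng = stage_rng(config.seed, "origins")
    n = config.n_origins
    cores = _timing_cores(genome, config.timing_overlap_bp)
    tss_df = genome.tracks["tss"].df
    excluded = genome.tracks["excluded"].df

    # timing class of each TSS (core domains only; TSS in overlap margins are
    # left out of the pools so class constraints stay exact)
    tss_class = {}
    for cls, spans in cores.items():
        for chrom, s, e in spans:
            sub = tss_df[(tss_df["chrom"] == chrom)
                         & (tss_df["start"] >= s) & (tss_df["start"] < e)]
            for idx in sub.index:
                tss_class.setdefault(idx, cls)
    pools: dict[str, list[int]] = {c: [] for c in TIMING_CLASSES}
    for idx, cls in tss_class.items():
        pools[cls].append(idx)
    for cls in pools:
        pools[cls] = list(rng.permutation(pools[cls]))

    at_tss = rng.random(n) < config.frac_origins_at_tss
    early = rng.random(n) < config.frac_origins_early

    def _draw_class(is_early: bool) -> str:
        weights = _EARLY_WEIGHTS if is_early else _LATE_WEIGHTS
        names = list(weights)
        return names[rng.choice(len(names), p=np.array(list(weights.values())))]

    def _in_excluded(chrom: str, pos: int) -> bool:
        sub = excluded[excluded["chrom"] == chrom]
        return bool(((sub["start"] <= pos) & (sub["end"] > pos)).any())

    group_classes = {True: ["S1", "S2"], False: ["S3", "S4", "S5", "S6"]}

    def _pop_tss(cls: str, is_early: bool) -> int | None:
        """A TSS index for the class, falling back within the timing group."""
        if pools[cls]:
            return pools[cls].pop()
        for alt in group_classes[is_early]:
            if pools[alt]:
                return pools[alt].pop()
        return None

    records = []
    for i in range(n):
        cls = _draw_class(early[i])
        placed_at_tss = False
        pos = chrom = None
        idx = _pop_tss(cls, bool(early[i])) if at_tss[i] else None
        if idx is not None:
            row = tss_df.loc[idx]
            chrom = row["chrom"]
            cls = tss_class[idx]
            jitter = int(rng.integers(-config.tss_halfwidth + 100,
                                      config.tss_halfwidth - 100 + 1))
            pos = int(row["start"]) + jitter
            placed_at_tss = True
        else:
            if at_tss[i]:
                raise ValueError(
                    "more TSS-associated origins requested than TSS available "
                    f"in the {'early' if early[i] else 'late'} timing group"
                )
            spans = cores[cls]
            if not spans:
                raise ValueError(f"no placement sites left for timing class {cls}")
            for _attempt in range(200):
                chrom, s, e = spans[int(rng.integers(len(spans)))]
                pos = int(rng.integers(s, e))
                near_tss = tss_df[
                    (tss_df["chrom"] == chrom)
                    & (tss_df["start"].sub(pos).abs() < 2 * config.tss_halfwidth)
                ]
                if len(near_tss) == 0 and not _in_excluded(chrom, pos):
                    break
            else:
                raise ValueError(f"could not place origin in class {cls}")
        pos = int(np.clip(pos, 0, genome.chromosomes[chrom] - 1))
        records.append([chrom, pos, cls, placed_at_tss])

    # clustered subset: non-TSS satellites re-placed 1-5 kb from a partner of
    # the same timing group, preserving the configured TSS and early fractions
    n_clustered = int(round(config.frac_origins_clustered * n))
    non_tss = [i for i in range(n) if not records[i][3]]
    n_clustered = min(n_clustered, len(non_tss))
    if n_clustered:
        sat_idx = [non_tss[k] for k in rng.choice(len(non_tss), size=n_clustered,
                                                  replace=False)]
        sat_set = set(sat_idx)
        for i in sat_idx:
            partners = [
                j for j in range(n)
                if j not in sat_set and early[j] == early[i]
            ]
            if not partners:
                break
            j = partners[int(rng.integers(len(partners)))]
            chrom_j, pos_j, cls_j = records[j][0], records[j][1], records[j][2]
            shift = int(rng.integers(1_000, 5_000)) * (1 if rng.random() < 0.5 else -1)
            new_pos = int(np.clip(pos_j + shift, 0, genome.chromosomes[chrom_j] - 1))
            # stay inside the partner's class core so the satellite keeps its class
            for chrom_c, s_c, e_c in cores[cls_j]:
                if chrom_c == chrom_j and s_c <= pos_j < e_c:
                    new_pos = int(np.clip(new_pos, s_c, e_c - 1))
                    break
            records[i] = [chrom_j, new_pos, cls_j, False]

    fp = np.clip(config.firing_probability * rng.uniform(0.5, 1.5, size=n), 0.0, 1.0)
    if config.firing_probability in (0.0, 1.0):
        fp = np.full(n, config.firing_probability)

    germline = np.zeros(n, dtype=bool)
    n_germ = int(round(config.frac_origins_germline * n))
    if n_germ:
        germline[rng.choice(n, size=n_germ, replace=False)] = True

    g4_df = genome.tracks["g4"].df
    origins = pd.DataFrame(records, columns=["chrom", "position", "timing_class", "at_tss"])
    origins["firing_probability"] = fp
    origins["germline"] = germline
    has_g4 = np.zeros(n, dtype=bool)
    for i, row in enumerate(origins.itertuples(index=False)):
        sub = g4_df[g4_df["chrom"] == row.chrom]
        has_g4[i] = bool(
            ((sub["start"] < row.position + 500) & (sub["end"] > row.position - 500)).any()
        )
    origins["has_g4"] = has_g4
    origins = origins[
        ["chrom", "position", "firing_probability", "timing_class",
         "at_tss", "has_g4", "germline"]
    ]

    jump_rows = [
        (row.chrom, int(row.position), "+")
        for row in origins[origins["germline"]].itertuples(index=False)
    ]
    # decoy negative jumps, kept >= 25 kb from every origin
    pos_by_chrom = {c: s["position"].to_numpy() for c, s in origins.groupby("chrom")}
    chrom_names = list(genome.chromosomes)
    lengths = np.array([genome.chromosomes[c] for c in chrom_names], dtype=float)
    for _ in range(config.n_negative_jumps):
        for _attempt in range(500):
            ci = int(rng.choice(len(chrom_names), p=lengths / lengths.sum()))
            chrom = chrom_names[ci]
            p = int(rng.integers(0, genome.chromosomes[chrom]))
            near = pos_by_chrom.get(chrom, np.empty(0))
            if len(near) == 0 or np.abs(near - p).min() >= 25_000:
                jump_rows.append((chrom, p, "-"))
                break
    jumps = pd.DataFrame(jump_rows, columns=["chrom", "position", "polarity"])
    return SimulationTruth(origins=origins.reset_index(drop=True), jumps=jumps)


# ---------------------------------------------------------------------------
# Read library simulation
# ---------------------------------------------------------------------------

def _truncated_rates(rng: np.random.Generator, n: int, config: SimConfig) -> np.ndarray:
    """Fork rates ~ Normal(mean, sd) truncated below at 1 bp/min."""
    if n == 0:
        return np.empty(0)
    a = (1.0 - config.fork_rate_mean) / config.fork_rate_sd
    return truncnorm.rvs(
        a, np.inf, loc=config.fork_rate_mean, scale=config.fork_rate_sd,
        size=n, random_state=rng,
    )


def _uniform_fragments(
    rng: np.random.Generator, genome: GenomeModel, n: int, config: SimConfig
) -> pd.DataFrame:
    chrom_names = list(genome.chromosomes)
    lengths = np.array([genome.chromosomes[c] for c in chrom_names], dtype=float)
    ci = rng.choice(len(chrom_names), size=n, p=lengths / lengths.sum())
    frag_len = rng.integers(config.fragment_min, config.fragment_max + 1, size=n)
    starts = np.empty(n, dtype=np.int64)
    ends = np.empty(n, dtype=np.int64)
    for k in range(n):
        L = int(lengths[ci[k]])
        fl = int(min(frag_len[k], L))
        s = int(rng.integers(0, L - fl + 1))
        starts[k], ends[k] = s, s + fl
    return pd.DataFrame(
        {
            "chrom": [chrom_names[i] for i in ci],
            "start": starts,
            "end": ends,
            "strand": np.where(rng.random(n) < 0.5, "+", "-"),
        }
    )


def _ip_library(
    rng: np.random.Generator,
    genome: GenomeModel,
    truth: SimulationTruth,
    config: SimConfig,
    efficiency: float,
    name: str,
) -> ReadLibrary:
    frames: list[pd.DataFrame] = []
    mean_len = config.mean_fragment_length
    for row in truth.origins.itertuples(index=False):
        chrom_len = genome.chromosomes[row.chrom]
        n_fire = int(rng.binomial(config.n_nuclei, row.firing_probability))
        if n_fire == 0:
            continue
        t = rng.uniform(0.0, config.max_lag, size=n_fire)
        dur = config.labelling_time - t
        # two tracts per firing, independent rates
        rates = _truncated_rates(rng, 2 * n_fire, config).reshape(2, n_fire)
        len_left = rates[0] * dur
        len_right = rates[1] * dur
        for side, lens in (("L", len_left), ("R", len_right)):
            n_frag = rng.poisson(efficiency * lens / mean_len)
            total = int(n_frag.sum())
            if total == 0:
                continue
            tract_len = np.repeat(lens, n_frag)
            u = rng.uniform(0.0, 1.0, size=total)
            offset = (u * tract_len).astype(np.int64)
            mid = row.position - offset if side == "L" else row.position + offset
            frag_len = rng.integers(config.fragment_min, config.fragment_max + 1,
                                    size=total)
            start = mid - frag_len // 2
            end = start + frag_len
            start = np.clip(start, 0, chrom_len - 1)
            end = np.clip(end, start + 1, chrom_len)
            frames.append(
                pd.DataFrame(
                    {
                        "chrom": row.chrom,
                        "start": start,
                        "end": end,
                        "strand": np.where(rng.random(total) < 0.5, "+", "-"),
                    }
                )
            )
    n_signal = int(sum(len(f) for f in frames))
    f_bg = config.s_phase_background_fraction
    if n_signal and 0 < f_bg < 1:
        n_bg = int(round(n_signal * f_bg / (1.0 - f_bg)))
        if n_bg:
            frames.append(_uniform_fragments(rng, genome, n_bg, config))
    if not frames:
        return ReadLibrary(name)
    df = pd.concat(frames, ignore_index=True)
    df = df.sort_values(["chrom", "start", "end"]).reset_index(drop=True)
    return ReadLibrary(name, df)


def simulate_libraries(
    genome: GenomeModel, truth: SimulationTruth, config: SimConfig
) -> tuple[ReadLibrary, ReadLibrary, ReadLibrary]:
    """Simulate the two IP replicate libraries and the uniform input library.

    Replicates differ only by IP efficiency: the expected number of
    fragments recovered per labelled tract scales with
    ``ip_efficiency_A`` / ``ip_efficiency_B``.  Deterministic per seed.
    """
    for row in truth.origins.itertuples(index=False):
        if row.chrom not in genome.chromosomes or not (
            0 <= row.position < genome.chromosomes[row.chrom]
        ):
            raise ValueError(f"truth origin outside genome: {row.chrom}:{row.position}")
    rng_a = stage_rng(config.seed, "reads-ip-a")
    rng_b = stage_rng(config.seed, "reads-ip-b")
    rng_in = stage_rng(config.seed, "reads-input")
    ip_a = _ip_library(rng_a, genome, truth, config, config.ip_efficiency_A, "IP-A")
    ip_b = _ip_library(rng_b, genome, truth, config, config.ip_efficiency_B, "IP-B")
    input_df = _uniform_fragments(rng_in, genome, config.reads_input, config)
    input_df = input_df.sort_values(["chrom", "start", "end"]).reset_index(drop=True)
    return ip_a, ip_b, ReadLibrary("input", input_df)


# ---------------------------------------------------------------------------
# Truth output
# ---------------------------------------------------------------------------

def write_truth(truth: SimulationTruth, outdir: str | Path) -> dict[str, Path]:
    """Write origin and jump truth as BED6 plus a full origins TSV.

    The BED files round-trip through the package's BED reader; the TSV
    carries the per-origin attributes (firing probability, flags) that BED
    cannot.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    o = truth.origins
    origins_bed = pd.DataFrame(
        {
            "chrom": o["chrom"],
            "start": o["position"],
            "end": o["position"] + 1,
            "name": [f"origin_{i}" for i in range(len(o))],
            "score": (o["firing_probability"].astype(float) * 1000).round().astype(int),
            "strand": ".",
        }
    )
    j = truth.jumps
    jumps_bed = pd.DataFrame(
        {
            "chrom": j["chrom"],
            "start": j["position"],
            "end": j["position"] + 1,
            "name": [f"jump_{i}" for i in range(len(j))],
            "score": 0,
            "strand": j["polarity"],
        }
    )
    paths = {
        "origins_bed": outdir / "truth_origins.bed",
        "jumps_bed": outdir / "truth_jumps.bed",
        "origins_tsv": outdir / "truth_origins.tsv",
    }
    origins_bed.sort_values(["chrom", "start"]).to_csv(
        paths["origins_bed"], sep="\t", header=False, index=False
    )
    jumps_bed.sort_values(["chrom", "start"]).to_csv(
        paths["jumps_bed"], sep="\t", header=False, index=False
    )
    o.to_csv(paths["origins_tsv"], sep="\t", index=False)
    return paths


def truth_jump_track(truth: SimulationTruth) -> FeatureTrack:
    j = truth.jumps
    return FeatureTrack(
        "jumps",
        pd.DataFrame(
            {
                "chrom": j["chrom"],
                "start": j["position"],
                "end": j["position"] + 1,
                "name": [f"jump_{i}" for i in range(len(j))],
                "strand": j["polarity"],
            }
        ),
    )
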