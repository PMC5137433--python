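"""End-to-end pipeline driver: post-process -> call -> intersect -> randomise
-> overlap analytics, with a reproducibility manifest.

Every stage draws its randomness from the single global seed via per-stage
named streams, so reruns with the same configuration and inputs are
bit-identical and toggling one analysis never shifts another's results.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import io as gio
from .caller import CallerConfig, call_islands_no_input, call_islands_with_input, merge_adjacent
from .catalog import OriginSet, count_reciprocal, intersect_replicates, summarize_catalog
from .core import FeatureTrack
from .nulls import NullConfig, randomize
from .overlap import (
    annotate_origins,
    inter_origin_distances,
    jump_overlap_profile,
    timing_profile,
)
from .seqfeatures import G4Params, scan_g4_genome, skew_profile
from .simulate import (
    SimConfig,
    SimulationTruth,
    generate_genome,
    plant_origins,
    simulate_libraries,
    write_truth,
)

logger = logging.getLogger("oriscan")

ALL_ANALYSES = ("annotation", "timing", "distances", "venn", "jumps", "g4", "skew")


@dataclass
class RunConfig:
    """Declarative description of one pipeline run."""

    chrom_sizes: str
    ip_a: str
    ip_b: str
    input_lib: str | None = None
    fasta: str | None = None
    genes: str | None = None
    tss: str | None = None
    exons: str | None = None
    timing: str | None = None
    excluded: str | None = None
    jumps: str | None = None
    outdir: str = "oriscan_out"
    caller: CallerConfig = field(default_factory=CallerConfig)
    use_input: bool = False
    jitter_halfwidth: int = 240_000
    analyses: tuple[str, ...] = ALL_ANALYSES
    tss_halfwidth: int = 500
    distance_bin: int = 5_000
    skew_window: int = 1_000
    seed: int = 0

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        caller = CallerConfig(**raw.pop("caller", {}))
        if "analyses" in raw:
            raw["analyses"] = tuple(raw["analyses"])
        return cls(caller=caller, **raw)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def _write_origins_bed(origins: OriginSet, path: Path) -> None:
    df = origins.df
    out = pd.DataFrame(
        {
            "chrom": df["chrom"],
            "start": df["start"],
            "end": df["end"],
            "name": [f"origin_{i}" for i in range(len(df))],
            "score": 0,
            "strand": ".",
        }
    )
    out.to_csv(path, sep="\t", header=False, index=False)


def _write_islands_bed(islands: pd.DataFrame, path: Path) -> None:
    out = pd.DataFrame(
        {
            "chrom": islands["chrom"],
            "start": islands["start"],
            "end": islands["end"],
            "name": [f"island_{i}" for i in range(len(islands))],
            "score": np.minimum(islands["score"], 1000).round(2),
            "strand": ".",
            "tag_count": islands["tag_count"],
            "significance": islands.get("significance", pd.Series(["."] * len(islands))),
        }
    )
    out.to_csv(path, sep="\t", header=False, index=False)


def run_pipeline(cfg: RunConfig) -> dict:
    """Run the configured stages; returns a report dict (also written to disk)."""
    outdir = Path(cfg.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    report: dict = {"outputs": {}, "stages": []}

    def _stage(name: str):
        logger.info("stage: %s", name)
        report["stages"].append(name)

    # ---- load inputs -------------------------------------------------
    _stage("load")
    genome = gio.read_chrom_sizes(cfg.chrom_sizes)
    lib_a = gio.read_tags_bed(cfg.ip_a, "IP-A")
    lib_b = gio.read_tags_bed(cfg.ip_b, "IP-B")
    input_lib = gio.read_tags_bed(cfg.input_lib, "input") if cfg.input_lib else None
    tracks: dict[str, FeatureTrack] = {}
    for label, path in [
        ("genes", cfg.genes), ("tss", cfg.tss), ("exons", cfg.exons),
        ("timing", cfg.timing), ("excluded", cfg.excluded), ("jumps", cfg.jumps),
    ]:
        if path:
            tracks[label] = gio.read_intervals_bed(path, genome, label=label)

    # ---- post-process ------------------------------------------------
    _stage("postprocess")
    lib_a = gio.deduplicate_tags(lib_a, cfg.caller.redundancy_threshold)
    lib_b = gio.deduplicate_tags(lib_b, cfg.caller.redundancy_threshold)
    if "excluded" in tracks:
        lib_a = gio.filter_excluded(lib_a, tracks["excluded"])
        lib_b = gio.filter_excluded(lib_b, tracks["excluded"])
    if input_lib is not None:
        input_lib = gio.deduplicate_tags(input_lib, cfg.caller.redundancy_threshold)
        if "excluded" in tracks:
            input_lib = gio.filter_excluded(input_lib, tracks["excluded"])

    # ---- call --------------------------------------------------------
    _stage("call")
    caller = cfg.caller
    if cfg.use_input:
        if input_lib is None:
            raise ValueError("use_input=True but no input library configured")
        islands_a = call_islands_with_input(lib_a, input_lib, genome, caller)
        islands_b = call_islands_with_input(lib_b, input_lib, genome, caller)
    else:
        islands_a = call_islands_no_input(lib_a, genome, caller)
        islands_b = call_islands_no_input(lib_b, genome, caller)
    islands_a = merge_adjacent(islands_a, caller)
    islands_b = merge_adjacent(islands_b, caller)
    _write_islands_bed(islands_a, outdir / "islands_A.bed")
    _write_islands_bed(islands_b, outdir / "islands_B.bed")

    # ---- intersect ---------------------------------------------------
    _stage("intersect")
    origins = intersect_replicates(
        islands_a, islands_b,
        provenance={"libraries": [lib_a.name, lib_b.name], "mode":
                    "with_input" if cfg.use_input else "no_input"},
    )
    _write_origins_bed(origins, outdir / "origins.bed")
    summary = summarize_catalog(origins, genome, lib_a, lib_b)
    with open(outdir / "catalog_summary.json", "w") as fh:
        json.dump(summary.to_dict(), fh, indent=2)
    report["n_origins"] = len(origins)
    report["venn_replicates"] = dict(zip(
        ["n_a_hit", "n_a_only", "n_b_hit", "n_b_only"],
        count_reciprocal(islands_a, islands_b),
    ))

    # ---- randomise ---------------------------------------------------
    _stage("randomise")
    null_chrom = randomize(origins, genome,
                           NullConfig(mode="chromosome", seed=cfg.seed))
    null_jitter = randomize(
        origins, genome,
        NullConfig(mode="timing_jitter", jitter_halfwidth=cfg.jitter_halfwidth,
                   seed=cfg.seed),
    )
    _write_origins_bed(null_chrom, outdir / "null_chromosome.bed")
    _write_origins_bed(null_jitter, outdir / "null_timing.bed")

    # ---- analytics ---------------------------------------------------
    sets = {"origins": origins, "null_chromosome": null_chrom,
            "null_timing": null_jitter}
    if "annotation" in cfg.analyses and all(
        k in tracks for k in ("genes", "tss", "exons")
    ):
        _stage("annotation")
        ann = {
            name: annotate_origins(s, tracks["genes"], tracks["tss"],
                                   tracks["exons"], cfg.tss_halfwidth).to_dict()
            for name, s in sets.items()
        }
        with open(outdir / "annotation.json", "w") as fh:
            json.dump(ann, fh, indent=2)
        report["annotation"] = ann["origins"]
    if "timing" in cfg.analyses and "timing" in tracks:
        _stage("timing")
        frames = []
        for name, s in sets.items():
            tp = timing_profile(s, tracks["timing"]).to_frame()
            tp["set"] = name
            frames.append(tp.reset_index())
        pd.concat(frames).to_csv(outdir / "timing_profile.tsv", sep="\t", index=False)
    if "distances" in cfg.analyses:
        _stage("distances")
        rows = []
        for name, s in sets.items():
            h = inter_origin_distances(s, cfg.distance_bin)
            for k, c in enumerate(h.counts):
                rows.append((name, k * cfg.distance_bin, (k + 1) * cfg.distance_bin, int(c)))
        pd.DataFrame(rows, columns=["set", "bin_start", "bin_end", "count"]).to_csv(
            outdir / "distances.tsv", sep="\t", index=False
        )
    if "jumps" in cfg.analyses and "jumps" in tracks:
        _stage("jumps")
        frames = []
        for name, s in sets.items():
            prof = jump_overlap_profile(s, tracks["jumps"])
            prof["set"] = name
            frames.append(prof)
        pd.concat(frames).to_csv(outdir / "jump_overlap.tsv", sep="\t", index=False)
    if cfg.fasta and ("g4" in cfg.analyses or "skew" in cfg.analyses):
        seqs = gio.read_fasta(cfg.fasta)
        if "g4" in cfg.analyses:
            _stage("g4")
            g4 = scan_g4_genome(seqs, G4Params())
            gio.write_intervals_bed(g4, outdir / "g4_motifs.bed")
            report["n_g4_motifs"] = len(g4)
        if "skew" in cfg.analyses:
            _stage("skew")
            rows = []
            for chrom, seq in seqs.items():
                prof = skew_profile(seq, cfg.skew_window)
                ends = np.minimum(prof.starts + cfg.skew_window, len(seq))
                rows.append(pd.DataFrame({
                    "chrom": chrom, "start": prof.starts, "end": ends,
                    "value": np.round(prof.values, 6),
                }))
            pd.concat(rows).to_csv(outdir / "skew.bedgraph", sep="\t",
                                   header=False, index=False)

    # ---- manifest ----------------------------------------------------
    _stage("manifest")
    manifest = {
        "seed": cfg.seed,
        "caller": asdict(cfg.caller),
        "inputs": {},
        "outputs": {},
    }
    for key in ("chrom_sizes", "ip_a", "ip_b", "input_lib", "fasta", "genes",
                "tss", "exons", "timing", "excluded", "jumps"):
        p = getattr(cfg, key)
        if p:
            manifest["inputs"][key] = _sha256(Path(p))
    for p in sorted(outdir.iterdir()):
        if p.name != "manifest.json" and p.is_file():
            manifest["outputs"][p.name] = _sha256(p)
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    report["outputs"] = {p.name: str(p) for p in sorted(outdir.iterdir())}
    with open(outdir / "report.json", "w") as fh:
        json.dump(report, fh, indent=2, default=str)
    return report


# ---------------------------------------------------------------------------
# Simulation-backed evaluation
# ---------------------------------------------------------------------------

def origin_recall(origins: OriginSet, truth: SimulationTruth,
                  min_firing: float = 0.0) -> float:
    """Fraction of planted origins (firing prob >= min_firing) covered by a call."""
    sel = truth.origins[truth.origins["firing_probability"] >= min_firing]
    if len(sel) == 0:
        return float("nan")
    hits = 0
    by_chrom = {c: s for c, s in origins.df.groupby("chrom", sort=False)}
    for row in sel.itertuples(index=False):
        sub = by_chrom.get(row.chrom)
        if sub is None:
            continue
        if ((sub["start"] <= row.position) & (sub["end"] > row.position)).any():
            hits += 1
    return hits / len(sel)


def origin_precision_proxy(origins: OriginSet, truth: SimulationTruth,
                           config: SimConfig) -> float:
    """Fraction of called origins within labelled-tract reach of a planted origin."""
    if len(origins) == 0:
        return float("nan")
    reach = config.labelling_time * (config.fork_rate_mean + 4 * config.fork_rate_sd)
    reach += config.fragment_max
    ok = 0
    pos_by_chrom = {c: s["position"].to_numpy()
                    for c, s in truth.origins.groupby("chrom")}
    for row in origins.df.itertuples(index=False):
        pos = pos_by_chrom.get(row.chrom, np.empty(0))
        if len(pos) == 0:
            continue
        mid = (row.start + row.end) // 2
        if np.abs(pos - mid).min() <= reach:
            ok += 1
    return ok / len(origins)


def simulate_and_run(sim: SimConfig, outdir: str | Path,
                     caller: CallerConfig | None = None,
                     analyses: tuple[str, ...] = ALL_ANALYSES) -> dict:
    """Generate a synthetic dataset, run the full pipeline on it, and score
    the resulting catalogue against the planted truth."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    genome = generate_genome(sim)
    truth = plant_origins(genome, sim)
    ip_a, ip_b, input_lib = simulate_libraries(genome, truth, sim)

    gio.write_chrom_sizes(genome, outdir / "genome.chrom.sizes")
    gio.write_fasta(genome, outdir / "genome.fa")
    for label in ("genes", "tss", "exons", "timing", "excluded"):
        gio.write_intervals_bed(genome.tracks[label], outdir / f"{label}.bed")
    gio.write_tags_bed(ip_a, outdir / "ip_a.bed")
    gio.write_tags_bed(ip_b, outdir / "ip_b.bed")
    gio.write_tags_bed(input_lib, outdir / "input.bed")
    truth_paths = write_truth(truth, outdir)

    run_cfg = RunConfig(
        chrom_sizes=str(outdir / "genome.chrom.sizes"),
        ip_a=str(outdir / "ip_a.bed"),
        ip_b=str(outdir / "ip_b.bed"),
        input_lib=str(outdir / "input.bed"),
        fasta=str(outdir / "genome.fa"),
        genes=str(outdir / "genes.bed"),
        tss=str(outdir / "tss.bed"),
        exons=str(outdir / "exons.bed"),
        timing=str(outdir / "timing.bed"),
        excluded=str(outdir / "excluded.bed"),
        jumps=str(truth_paths["jumps_bed"]),
        outdir=str(outdir / "pipeline"),
        caller=caller or CallerConfig(seed=sim.seed),
        analyses=analyses,
        seed=sim.seed,
    )
    report = run_pipeline(run_cfg)

    origins = OriginSet(gio.read_intervals_bed(
        Path(run_cfg.outdir) / "origins.bed").df[["chrom", "start", "end"]])
    evaluation = {
        "n_planted": len(truth),
        "n_called": len(origins),
        "recall_all": origin_recall(origins, truth),
        "recall_efficient": origin_recall(origins, truth,
                                          min_firing=sim.firing_probability),
        "precision_proxy": origin_precision_proxy(origins, truth, sim),
    }
    report["evaluation"] = evaluation
    with open(outdir / "evaluation.json", "w") as fh:
        json.dump(evaluation, fh, indent=2)
    return report
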