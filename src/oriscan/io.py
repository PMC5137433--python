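"""Readers and writers for the plain-text genomics formats the pipeline uses.

chrom.sizes and BED files are tab-separated text and are read/written with
pandas; FASTA is written with Bio.SeqIO and read with pyfaidx.  Everything
written by this module reads back to the identical in-memory value.
"""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord
from pyfaidx import Fasta

from .core import FeatureTrack, GenomeModel, ReadLibrary, overlaps_any

logger = logging.getLogger("oriscan")


def read_chrom_sizes(path: str | Path) -> GenomeModel:
    """Read a two-column ``chrom<TAB>length`` table into a genome skeleton."""
    chroms: dict[str, int] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) != 2:
                raise ValueError(f"{path}:{lineno}: expected 2 columns, got {len(fields)}")
            name, raw = fields
            if name in chroms:
                raise ValueError(f"{path}:{lineno}: duplicate chromosome {name!r}")
            try:
                length = int(raw)
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: non-integer length {raw!r}") from exc
            if length <= 0:
                raise ValueError(f"{path}:{lineno}: non-positive length for {name!r}")
            chroms[name] = length
    return GenomeModel(chromosomes=chroms)


def write_chrom_sizes(genome: GenomeModel, path: str | Path) -> None:
    with open(path, "w") as fh:
        for name, length in genome.chromosomes.items():
            fh.write(f"{name}\t{length}\n")


def read_intervals_bed(
    path: str | Path,
    genome: GenomeModel | None = None,
    label: str | None = None,
    strict: bool = False,
) -> FeatureTrack:
    """Read BED3–BED6 into a FeatureTrack.

    Records on chromosomes absent from ``genome`` are skipped with a logged
    count (``strict=True`` raises instead), mirroring how liftover debris is
    usually handled.
    """
    path = Path(path)
    names = ["chrom", "start", "end", "name", "score", "strand"]
    try:
        raw = pd.read_csv(
            path, sep="\t", header=None, comment="#", dtype={0: str}, usecols=range(6),
            names=names,
        )
    except (pd.errors.EmptyDataError, ValueError):
        try:
            raw = pd.read_csv(path, sep="\t", header=None, comment="#", dtype={0: str})
        except pd.errors.EmptyDataError:
            return FeatureTrack(label or path.stem)
        raw.columns = names[: raw.shape[1]]
    if "name" not in raw.columns:
        raw["name"] = "."
    if "strand" not in raw.columns:
        raw["strand"] = "."
    raw["name"] = raw["name"].fillna(".").astype(str)
    raw["strand"] = raw["strand"].fillna(".").astype(str)
    df = raw[["chrom", "start", "end", "name", "strand"]].copy()
    if (df["start"] >= df["end"]).any():
        bad = df[df["start"] >= df["end"]].iloc[0]
        raise ValueError(f"{path}: start >= end at {bad['chrom']}:{bad['start']}")
    if genome is not None:
        known = df["chrom"].isin(genome.chromosomes)
        if not known.all():
            n_bad = int((~known).sum())
            if strict:
                raise ValueError(f"{path}: {n_bad} records on unknown chromosomes")
            logger.warning("%s: skipped %d records on unknown chromosomes", path, n_bad)
            df = df[known].reset_index(drop=True)
        track = FeatureTrack(label or path.stem, df)
        track.validate_against(genome)
        return track
    return FeatureTrack(label or path.stem, df)


def write_intervals_bed(
    track: FeatureTrack,
    path: str | Path,
    score: pd.Series | np.ndarray | None = None,
    extra: pd.DataFrame | None = None,
) -> None:
    """Write a track as BED6 (plus optional extra columns), sorted as given."""
    df = track.df.copy()
    df["score"] = 0 if score is None else np.asarray(score)
    out = df[["chrom", "start", "end", "name", "score", "strand"]]
    if extra is not None:
        out = pd.concat([out.reset_index(drop=True), extra.reset_index(drop=True)], axis=1)
    out.to_csv(path, sep="\t", header=False, index=False)


def write_bedgraph(
    chrom: np.ndarray, start: np.ndarray, end: np.ndarray, value: np.ndarray,
    path: str | Path,
) -> None:
    pd.DataFrame({"chrom": chrom, "start": start, "end": end, "value": value}).to_csv(
        path, sep="\t", header=False, index=False
    )


def read_tags_bed(path: str | Path, name: str | None = None) -> ReadLibrary:
    track = read_intervals_bed(path)
    df = track.df[["chrom", "start", "end", "strand"]]
    return ReadLibrary(name or Path(path).stem, df)


def write_tags_bed(lib: ReadLibrary, path: str | Path) -> None:
    df = lib.df.copy()
    df["name"] = "."
    df["score"] = 0
    df[["chrom", "start", "end", "name", "score", "strand"]].to_csv(
        path, sep="\t", header=False, index=False
    )


def write_fasta(genome: GenomeModel, path: str | Path) -> None:
    if genome.sequences is None:
        raise ValueError("genome has no sequences to write")
    records = [
        SeqRecord(Seq(genome.sequences[name]), id=name, description="")
        for name in genome.chromosomes
    ]
    SeqIO.write(records, str(path), "fasta")


def read_fasta(path: str | Path) -> dict[str, str]:
    fa = Fasta(str(path), as_raw=True, sequence_always_upper=True, rebuild=True)
    return {name: str(fa[name][:]) for name in fa.keys()}


# ---------------------------------------------------------------------------
# Library post-processing
# ---------------------------------------------------------------------------

def deduplicate_tags(lib: ReadLibrary, redundancy_threshold: int = 1) -> ReadLibrary:
    """Keep at most ``redundancy_threshold`` tags per (chrom, start, strand).

    First occurrences are retained in input order, matching how duplicate
    reads are removed before island calling.
    """
    if redundancy_threshold < 1:
        raise ValueError("redundancy_threshold must be >= 1")
    df = lib.df
    rank = df.groupby(["chrom", "start", "strand"], sort=False).cumcount()
    return ReadLibrary(lib.name, df[rank < redundancy_threshold].reset_index(drop=True))


def filter_excluded(lib: ReadLibrary, excluded: FeatureTrack) -> ReadLibrary:
    """Drop every tag overlapping (>=1 bp) a blacklisted interval."""
    if len(excluded) == 0 or len(lib) == 0:
        return ReadLibrary(lib.name, lib.df.copy())
    hit = overlaps_any(lib.df, excluded.df)
    return ReadLibrary(lib.name, lib.df[~hit].reset_index(drop=True))
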