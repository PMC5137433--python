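"""Shared fixtures: a tiny hand-built genome and one default synthetic run.

The default synthetic bundle (genome, planted truth, libraries, called
islands, replicate-intersect catalogue) is expensive enough to build once
per session and is reused by the overlap, null-model and acceptance tests.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import pytest

from oriscan import (
    CallerConfig,
    GenomeModel,
    OriginSet,
    SimConfig,
    call_islands_no_input,
    deduplicate_tags,
    filter_excluded,
    generate_genome,
    intersect_replicates,
    merge_adjacent,
    plant_origins,
    simulate_libraries,
)

DEFAULT_SEED = 1


@pytest.fixture(scope="session")
def tiny_genome() -> GenomeModel:
    return GenomeModel(chromosomes={"chrA": 10_000, "chrB": 6_000})


@dataclass
class SimBundle:
    sim: SimConfig
    caller: CallerConfig
    genome: object
    truth: object
    lib_a: object
    lib_b: object
    lib_input: object
    islands_a: pd.DataFrame
    islands_b: pd.DataFrame
    origins: OriginSet


@pytest.fixture(scope="session")
def sim_bundle() -> SimBundle:
    """Default study conditions: 200 origins, firing prob 0.3, 3.5% background,
    IP-A at half the IP efficiency of IP-B."""
    sim = SimConfig(seed=DEFAULT_SEED)
    caller = CallerConfig(seed=DEFAULT_SEED)
    genome = generate_genome(sim)
    truth = plant_origins(genome, sim)
    lib_a, lib_b, lib_input = simulate_libraries(genome, truth, sim)
    da = filter_excluded(deduplicate_tags(lib_a, caller.redundancy_threshold),
                         genome.tracks["excluded"])
    db = filter_excluded(deduplicate_tags(lib_b, caller.redundancy_threshold),
                         genome.tracks["excluded"])
    islands_a = merge_adjacent(call_islands_no_input(da, genome, caller), caller)
    islands_b = merge_adjacent(call_islands_no_input(db, genome, caller), caller)
    origins = intersect_replicates(islands_a, islands_b)
    return SimBundle(sim, caller, genome, truth, lib_a, lib_b, lib_input,
                     islands_a, islands_b, origins)


@pytest.fixture(scope="session")
def truth_catalog(sim_bundle) -> OriginSet:
    """The planted origins as an interval catalogue (+/- 1.5 kb around each)."""
    o = sim_bundle.truth.origins
    lengths = sim_bundle.genome.chromosomes
    df = pd.DataFrame(
        {
            "chrom": o["chrom"],
            "start": np.maximum(o["position"] - 1_500, 0),
            "end": [
                min(p + 1_500, lengths[c]) for c, p in zip(o["chrom"], o["position"])
            ],
        }
    )
    return OriginSet(df)


def random_track_df(rng: np.random.Generator, n: int,
                    chroms: dict[str, int], max_width: int = 500) -> pd.DataFrame:
    names = list(chroms)
    ci = rng.integers(0, len(names), size=n)
    starts = np.array([rng.integers(0, chroms[names[i]] - max_width) for i in ci])
    widths = rng.integers(1, max_width, size=n)
    return pd.DataFrame(
        {
            "chrom": [names[i] for i in ci],
            "start": starts,
            "end": starts + widths,
        }
    )
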