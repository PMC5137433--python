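"""Genic annotation of the catalogue and skew-jump overlap profiles.

Each origin gets exactly one category with priority TSS > exon > intron >
intergenic.  Skew jumps (positive = putative germline origin; negative =
termination-associated) are tested for an origin within nested windows of
2-40 kb around the jump nucleotide.
"""

from oriscan import (
    NullConfig, SimConfig, annotate_origins, generate_genome,
    jump_overlap_profile, plant_origins, randomize_within_chromosome,
    simulate_libraries, OriginSet,
)
from oriscan.simulate import truth_jump_track
import numpy as np
import pandas as pd

sim = SimConfig(seed=1)
genome = generate_genome(sim)
truth = plant_origins(genome, sim)
o = truth.origins
catalog = OriginSet(pd.DataFrame({
    "chrom": o["chrom"],
    "start": np.maximum(o["position"] - 1_500, 0),
    "end": o["position"] + 1_500,
}))

ann = annotate_origins(catalog, genome.tracks["genes"], genome.tracks["tss"],
                       genome.tracks["exons"], tss_halfwidth=500)
print("annotation fractions:", ann.fractions.round(3).to_dict())

jumps = truth_jump_track(truth)
real = jump_overlap_profile(catalog, jumps)
null = jump_overlap_profile(
    randomize_within_chromosome(catalog, genome, NullConfig(seed=3)), jumps
)
print("\njump overlap fraction by window size (kb):")
for pol in ["+", "-"]:
    r = real[real["polarity"] == pol].set_index("window_size")["fraction"]
    n = null[null["polarity"] == pol].set_index("window_size")["fraction"]
    print(f"  {pol} jumps   real: "
          + "  ".join(f"{w//1000}k:{v:.2f}" for w, v in r.items()))
    print(f"  {pol} jumps   null: "
          + "  ".join(f"{w//1000}k:{v:.2f}" for w, v in n.items()))
print("\nreading: + jumps sit on planted germline origins, so their overlap "
      "is far above the randomised control at every window; - jumps were "
      "planted away from origins and stay at or below it.")
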