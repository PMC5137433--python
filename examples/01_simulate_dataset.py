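"""Generate a synthetic ini-seq-style dataset and inspect its structure.

Builds a two-chromosome toy genome (11.5 Mb) with genes, an S1-S6
replication-timing landscape, planted G4 motifs and excluded regions, plants
200 replication origins with the default structure (50% at TSS, 75% early,
20% clustered), and simulates the two IP replicate libraries plus a uniform
input library.
"""

from oriscan import SimConfig, generate_genome, plant_origins, simulate_libraries

sim = SimConfig(seed=1)
genome = generate_genome(sim)
truth = plant_origins(genome, sim)
ip_a, ip_b, input_lib = simulate_libraries(genome, truth, sim)

o = truth.origins
print(f"genome: {len(genome.chromosomes)} chromosomes, "
      f"{genome.total_length/1e6:.2f} Mb, {len(genome.tracks['genes'])} genes")
print(f"planted origins: {len(o)}")
print(f"  at TSS:        {o['at_tss'].mean():.2f}  (target 0.50)")
print(f"  early (S1/S2): {o['timing_class'].isin(['S1', 'S2']).mean():.2f}  (target 0.75)")
print(f"  germline (+ skew jump): {o['germline'].sum()}")
print(f"  firing probability range: {o['firing_probability'].min():.2f}"
      f"-{o['firing_probability'].max():.2f}")
print(f"libraries: IP-A {len(ip_a)} tags, IP-B {len(ip_b)} tags "
      f"(A/B = {len(ip_a)/len(ip_b):.2f}; IP-A is the less efficient replicate), "
      f"input {len(input_lib)} tags")
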