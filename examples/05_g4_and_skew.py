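"""G-quadruplex motif scanning and compositional skew on a small sequence.

The G4 motif is four runs of >=3 G separated by 1-7 nt loops (the C-run
pattern is reported as a minus-strand motif).  The compositional skew per
window is S = (T-A)/(T+A) + (G-C)/(G+C); an origin active in the germline
leaves an abrupt positive shift of S at its position.
"""

import numpy as np

from oriscan import G4Params, scan_g4, skew_profile

seq = ("ATATATTTTA" * 30          # T/A-rich: positive TA skew term
       + "GGGACGGGTTGGGACGGG"     # a canonical G4 motif
       + "CCCTACCCAACCCTACCC"     # its reverse-complement pattern
       + "GCGCGCGCGC" * 30)

track = scan_g4(seq, G4Params())
for r in track.df.itertuples(index=False):
    print(f"G4 motif on {r.strand} strand at [{r.start}, {r.end}): "
          f"{seq[r.start:r.end]}")

prof = skew_profile(seq, window=100)
print("\nskew S per 100-bp window:", np.round(prof.values, 2).tolist())
print("reading: the T-biased prefix gives a positive S; balanced "
      "GC-alternating sequence sits at 0.  S is bounded by [-2, 2].")
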