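# Methods

This note records the models, parameter choices and numerical conventions
behind `oriscan`, and what the synthetic-data experiments do and do not
demonstrate.

## Island calling model

Tags are counted in non-overlapping windows of `window_size` (default
150 bp) anchored at coordinate 0 of each chromosome; a trailing partial
window is kept and counted like any other. Each tag contributes at its
estimated fragment midpoint: `start + fragment_size/2` for + tags,
`end − fragment_size/2` for − tags (un-stranded tags are treated as +),
clipped into the chromosome so tag number is conserved.

The background model is a single genome-wide Poisson rate

    λ = total_tags × window_size / (effective_genome_fraction × genome_length).

`effective_genome_fraction` (default 0.793) models the mappable fraction of
a real genome. On fully-mappable synthetic genomes this makes λ an
overestimate of the true per-window rate, i.e. the caller is conservative
there; that bias direction is deliberate.

A window with count *k* is **eligible** when P(X ≥ *k*; λ) < `eligibility_p`
(default 0.2). Candidate islands are maximal runs of eligible windows
allowing at most `gap_size` consecutive ineligible windows inside (default
0); island score is Σ −ln P(kᵢ; λ) over the *eligible* member windows
(natural log; the base only rescales thresholds because calibration uses the
same base), and `tag_count` sums every window in the span, gap windows
included.

### E-value calibration

The score threshold s\* is the smallest value for which the expected number
of background islands with score ≥ s\*, over `n_windows` windows, is at most
`e_value`. Two estimators are provided:

* `recursion` (default, exact for gap 0): the score distribution of one
  eligible window is placed on a 0.01-score grid; the island-score density
  is Σₘ conv_m weighted by the boundary factor (1−q)², where q is the
  eligibility probability and conv_m the m-fold convolution; island lengths
  are truncated when the residual run probability falls below 10⁻¹² /
  n_windows. The expectation curve is the upper tail of that density times
  n_windows.
* `monte_carlo`: `mc_replicates` simulated genomes of Poisson(λ) counts,
  islands scored against the analytic λ, and the threshold read off the
  pooled score ranks.

The two agree to within a few percent at the calibration scales used in the
tests. `n_windows` is the actual number of scanned windows (λ, not
n_windows, carries the effective-genome-fraction correction). Islands whose
score equals s\* exactly are retained.

### With-input (FDR) mode

Candidates are the raw `find_islands` runs (no E-value pre-filter; applying
the score filter first would leave the FDR step nothing to decide on strong
data). Each candidate's significance is the upper Poisson tail of its IP
tag count with mean = (input tags in the same span, floored at a pseudocount
of 1) × (IP library size / input library size), followed by
Benjamini–Hochberg over all candidates at `fdr`.

### Post-merge

Called islands on the same chromosome separated by at most one window
(150 bp) are merged, summing scores and tag counts. The operation is
idempotent because a merged gap always exceeds one window.

## Replicate intersection

The catalogue is the base-pair intersection of the two island sets with
book-ended result pieces merged, so every catalogue interval lies inside an
island of each replicate. The alternative reading — keeping full replicate
spans that overlap — is not implemented as a default because the catalogue
is described as regions *present in both* libraries. Tags per origin are
recomputed by counting tag midpoints inside the final spans, making the
summary independent of caller internals.

## Randomised nulls

Both modes preserve each origin's chromosome and width exactly and draw
each origin independently (no joint permutation; null origins may overlap
each other):

* `chromosome`: start redrawn uniformly; placements that would extend past
  the chromosome end are redrawn (up to `max_redraws`, then an error naming
  the origin). This is distributionally identical to drawing directly from
  the valid range and is implemented as rejection sampling so the
  redraw-budget contract is explicit.
* `timing_jitter`: start shifted by a uniform offset in
  ±`jitter_halfwidth` (default 240,000 bp — half the 480-kb average width
  of an early replication-timing window), with the same redraw rule. The
  jitter destroys sub-5-kb clustering while approximately preserving the
  per-class timing percentages (within ~5 points on the default synthetic
  catalogue).

## Catalogue analytics

* **Annotation**: one category per origin, priority TSS > exon > intron >
  intergenic; a TSS hit is overlap with ±`tss_halfwidth` (default 500 bp)
  around the start-site nucleotide. Promoter-first priority reflects the
  biology the catalogue is meant to expose (origin–promoter colocation); a
  majority-coverage tie-break would change only origins spanning both a TSS
  window and a long exon.
* **Timing profile**: an origin counts in every S1–S6 class it overlaps by
  ≥ 1 nt, so percentages may sum above 100 (timing windows themselves
  overlap). Origins overlapping no timing window are reported separately.
* **Spacing**: per chromosome, successive midpoint-to-midpoint differences
  histogrammed in half-open bins of 5,000 bp (edge-to-edge distances are
  available behind `method="edge"`). Chromosomes with fewer than two
  origins contribute nothing.
* **Jump overlap**: each skew jump is collapsed to its midpoint nucleotide
  and surrounded by nested windows {2, 4, 6, 10, 20, 30, 40} kb; the
  fraction of jumps with ≥ 1 nt origin overlap is reported per polarity and
  is monotone non-decreasing in window size by construction.
* **G4 scanning**: regex-based, `G{3,}([ACGT]{1,7}?G{3,}){3}` on the +
  strand and the C-run equivalent reported as − strand, leftmost and
  non-re-entrant, with greedy runs and lazy (shortest-first) loops so each
  motif is the most compact representative at its locus. The loop bound
  1–7 nt follows the canonical quadparser convention; genome-wide motif
  counts are sensitive to this choice, so it is configurable. `N` never
  matches.
* **Skew**: S = (T−A)/(T+A) + (G−C)/(G+C) per non-overlapping window
  (default 1,000 bp) on the + strand; a zero-denominator term contributes
  0, so S ∈ [−2, 2] and an all-T window scores exactly 1. The trailing
  partial window is computed over its remaining bases and flagged.

## Synthetic-data generator

The generator reproduces the statistical structure the method relies on,
with the study's stated conditions as defaults:

| parameter | default | meaning |
|---|---|---|
| fork_rate_mean / sd | 300 / 200 bp/min | per-fork rate, normal truncated at 1 bp/min, one rate per fork |
| labelling_time | 15 min | labelling window |
| max_lag | 10 min | firing time ~ Uniform[0, max_lag] |
| s_phase_background_fraction | 0.035 | fraction of IP fragments placed uniformly genome-wide |
| fragment_min/max | 100 / 1000 bp | sonication fragment lengths, uniform |
| ip_efficiency_A / B | 0.5 / 1.0 | expected fragments per labelled tract scale with efficiency, so A has half B's per-origin depth |
| frac_origins_at_tss | 0.5 | planted TSS association |
| frac_origins_early | 0.75 | planted S1∪S2 preference |
| firing_probability | 0.3 | per-nucleus scale; per-origin value = scale × U(0.5, 1.5) clipped to [0, 1], exact at the 0/1 boundaries |
| n_origins / n_nuclei | 200 / 100 | catalogue and cohort size |

The per-origin firing probability is a free parameter of the in-vitro
system, not a measured value; 0.3 is a defensible middle ground between
"every origin fires in every nucleus" and the sparse firing seen in single-
molecule data.

The toy genome tiles each chromosome with a repeating S1→S6 cycle of 480-kb
domains, each extended 60 kb into its neighbours so adjacent classes
overlap; the default chromosome length (5,760,000 bp) is exactly two cycles,
giving every class an equal genomic share — which is what makes the
chromosome-null timing profile flat by construction rather than by tuning.
Genes occupy one equal-width slot each (guaranteeing non-overlap), with
lengths adapted to the slot; early origins are drawn S1:S2 = 0.6:0.4 and
late origins S3:S4:S5:S6 = 0.4:0.3:0.2:0.1, so the planted timing profile
decreases monotonically the way an early-S catalogue should. A clustered
subset (20%) of non-TSS origins is re-placed 1–5 kb from a partner of the
same timing group, preserving the configured TSS and early fractions
exactly. Germline origins (15%) emit a positive skew jump at their position;
decoy negative jumps are planted ≥ 25 kb from every origin. Canonical G4
motifs (G₃N₃G₃N₃G₃N₃G₃ with G-free loops and non-G guard bases) are written
into the sequence near 60% of TSS plus a few intergenic decoys.

**What the generator does not model**: sequencing errors and base
qualities (tags are emitted already placed), mappability structure, GC bias
in fragment recovery, heterogeneous (non-uniform) elongation background,
fork stalling or fusion of converging forks, and chromatin context. Passing
tests therefore demonstrate the correctness and calibration of the
computational pipeline under its own assumptions, not robustness to every
artefact of real libraries.

## Determinism and seeding

A single seed is split per stage by hashing the stage name into a
`SeedSequence`, so toggling one stochastic stage never shifts another's
stream and every output is bit-identical across reruns with the same
configuration and inputs (the pipeline manifest records input and output
checksums to make this checkable).

## Problem sizes used in validation

The test and acceptance runs use an 11.5-Mb two-chromosome genome with 200
planted origins (≈ 35–75k IP tags per replicate), 200 signal-free 10-Mb
simulations for background calibration, 500 Monte-Carlo replicates for the
threshold cross-check, and a pooled 5,000-origin catalogue (five plantings
on one genome) for the timing-profile recovery check, where a single
1,000-origin draw would leave the small S3→S4 step within sampling noise.
These sizes keep the whole suite fast while leaving every tested contrast
several standard errors wide.

## Known limitations

* The E-value recursion assumes gap 0 (the default); for gap > 0 the
  Monte-Carlo estimator is the appropriate null.
* The with-input mode inherits the input library's sampling noise; on
  shallow inputs the scaled-Poisson test can be anti-conservative in
  low-coverage spans (the pseudocount of 1 mitigates but does not remove
  this).
* Score thresholds are resolved on a 0.01 grid; thresholds are therefore
  exact only to that resolution.
* `intersect_replicates` supports two replicates; more replicates are
  handled by iterated pairwise application.
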