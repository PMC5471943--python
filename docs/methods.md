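# Methods

## Data model

A *dynamic network* is an ordered sequence of T symmetric, nonnegative
weighted adjacency matrices over one fixed electrode set N. Edge weights
are correlation magnitudes |r| (absolute Pearson correlation) between
electrode signals within an analysis window: the sign of a correlation is
discarded because community detection consumes connectivity *strength*, and
anticorrelated electrodes are as functionally coupled as correlated ones.
Windows are half-open `[start, start + window_length)` with a hop of
`round(window_length × (1 − overlap_fraction))` samples; timesteps are
0-based. A channel that is constant within a window has no defined
correlation; it receives weight 0 against every partner (with a logged
warning) rather than NaN, so downstream code never branches on missing
values.

Per-electrode *activation*, the quantity shown as glyph opacity, is not a
standard quantity with one agreed definition; this package defines it as the
per-window mean absolute amplitude (RMS available as an option), min-max
rescaled to [0, 1] globally over the whole recording so that levels are
comparable across electrodes and timesteps. A constant recording maps to
all zeros.

## Per-timestep community detection

Each timestep is clustered independently (no temporal coupling — see
Limitations). The feature vector of electrode i is row i of that timestep's
adjacency matrix, i.e. its connectivity profile; electrodes with similar
connectivity are similar points regardless of whether they are directly
connected.

**Consensus clustering.** For each candidate K in `[k_min, k_max]`
(default [2, 8]), `n_runs` (default 50) subsampled k-means runs are
performed, each on a uniform random `subsample_fraction` (default 0.8) of
electrodes, and combined into a consensus matrix

    M_K(i, j) = (# runs co-clustering i and j) / (# runs sampling both),

symmetric with unit diagonal; pairs never co-sampled (possible only at
extreme settings) get 0 with a warning. Each k-means run uses a single
initialization; run-to-run variability is the point of the resampling, and
the consensus averages it out. With `n_runs=1` and full sampling the matrix
is exactly binary.

**Degenerate inputs.** If all pairwise feature distances at a timestep are
equal (identical profiles, or a uniform complete graph, whose profiles form
a regular simplex), k-means has no structure to act on and any split it
returned would be an artifact of tie-breaking. Such timesteps are treated
as fully co-clustered: the consensus is all ones for every K, which triggers
the degenerate selection rule below.

**Selecting K.** The number of communities is chosen from the empirical CDF
of the off-diagonal consensus entries. The default statistic is the
*proportion of ambiguous clustering*,

    PAC(K) = CDF_K(0.9) − CDF_K(0.1),

the fraction of electrode pairs that are neither decisively together nor
decisively apart. The per-K likelihood shown in the K-cluster heatmap is
1 − PAC min-max rescaled to [0, 1] over the candidate range; the selected K
is the argmax, ties toward smaller K. The classic change-in-CDF-area
statistic (A(K) = area under CDF_K; Δ(K) = A(K) for the smallest candidate,
else (A(K) − A(K−1))/A(K−1)) is implemented and selectable with
`ConsensusParams(statistic="delta-area")`. PAC is the default because the
Δ rule compares an absolute area (at the smallest K) against relative
changes (above it), and on clean three-block data that comparison sits on a
knife edge: measured under this package's default conditions the margin
between Δ(2) and Δ(3) is about 0.02 with a standard deviation of about
0.01, i.e. a few percent of timesteps mis-select K = 2 purely by resampling
noise. PAC separates the same cases by a margin of ~0.5 and selects exactly
on two-community controls, at identical cost.

**Degenerate rule.** If the consensus is all ones (within
`identity_epsilon`, default 1e-6) for *every* candidate K, the electrodes
are indistinguishable: the likelihood profile is identically 0, the heatmap
column renders fully white, and K = 1 is selected (a single community).

**Final labels.** The consensus matrix at the selected K is itself a
similarity; labels come from average-linkage hierarchical clustering of the
distance 1 − M_K cut into K clusters, then canonicalized by descending
cluster size with ties broken by smallest member index, so equal inputs
yield bit-identical labels.

## Cluster tracking

Two matchers link clusters of consecutive timesteps:

* **Greedy maximum-overlap**: repeatedly pair the unmatched source/sink
  clusters sharing the most electrodes, until no unmatched pair shares any.
  Ties break row-major (smaller source index, then smaller sink index).
  The greedy matcher works on raw electrode counts and applies no
  similarity threshold.
* **Globally optimal**: Jaccard similarities below θ (default 0.1) are
  zeroed; over all injective assignments the one maximizing total
  similarity is returned, zero-similarity pairings left unmatched, ties
  resolved to the lexicographically smallest pair list. Reference
  semantics is exhaustive enumeration, tractable for the ≤ ~7 clusters per
  timestep this data produces; above 10 clusters per side the
  linear-assignment solver engine is required (it is verified equivalent on
  enumerable instances). Unequal cluster counts are handled as partial
  injective matchings.

A matched sink inherits its source's persistent community id; an unmatched
sink is a birth, an unmatched source a death. Ids are allocated in order of
first appearance and colored, in that order, from a qualitative ColorBrewer
palette (default Set1); beyond the palette size colors recycle with a
warning. Transition links — one per cluster pair sharing ≥ 1 electrode,
carrying the electrode count and Jaccard similarity — are computed for all
pairs independently of the matching, and conserve flow: per timestep pair
the counts sum to |N| on both the source and sink side.

## Timeline ordering

Exact crossing minimization is NP-hard, so block order per timestep comes
from the barycenter heuristic of layered graph drawing. The scored
objective is the total count-weighted vertical distance between linked
block centers (block heights ∝ cluster size, one height unit per
electrode); crossings are reported alongside but the smoother distance
objective drives optimization. Initial order is descending cluster size
(stable large communities at the top). Sweeps run forward then backward
within consecutive blocks of `block_size` timesteps (default 10, so a
30-timestep dataset is three blocks; a short final block is allowed),
reordering each timestep by the count-weighted barycenter of its linked
neighbors' current centers, ties placing larger clusters first. After each
full pass the objective is evaluated and a pass that would increase it is
reverted, making the objective non-increasing by construction; a final
adjacent-transposition hill climb per timestep (also strictly improving)
polishes the result. On small instances (≤ 4 clusters × 4 timesteps) the
result is within 1.2× the exhaustive optimum in the test suite's seeded
sample.

## Rendering

All views are pure functions of their inputs: fixed element order,
coordinates at two decimals, hence byte-identical SVG for identical inputs.

* *Alluvial view*: per timestep a vertical stack of rectangles (height ∝
  size, fill = community color); per transition link a ribbon of thickness
  ∝ electrode count drawn as two cubic Beziers with control points at the
  horizontal midpoint between the two columns (a fixed choice made for
  determinism). Edge segments within a block are allocated in neighbor
  position order, which keeps ribbons from crossing inside a block.
* *K-cluster heatmap*: grid of timesteps × candidate K, grayscale fill
  1 − likelihood (black = high likelihood); a degenerate timestep renders
  fully white.
* *Electrode views*: the timeline is partitioned into spans of
  `granularity` timesteps; views alternate above (x1) and below (x2) a
  central band carrying the alluvial view, left to right, x-offsets the
  cumulative view widths. Per-view width is w_i = w_min · S_f with
  S_f = C · W_max / (w_min · max(N_x1, N_x2)), required ≥ 1 (the error
  names the largest feasible w_min); when spans are unequal (a short final
  span) widths scale proportionally to span length. Each electrode is a
  clock glyph: one slice per timestep in the span, clockwise from
  12 o'clock, colored by the electrode's community and filled at opacity =
  activation; the outline circle is always drawn so fully-transparent
  glyphs remain visible. Coordinates (optionally restricted to a crop
  region) are mapped into each view by a uniform-scale affine map, so
  relative distances are preserved; an optional background raster is
  referenced as an underlay.

The original interactive workflow (brushing, focus+context, tooltips) is
out of scope; its role is filled by re-rendering with different
`--granularity` and `--interval` flags, plus the JSON scene dump.

## Synthetic generator

The default `SyntheticSpec` is the package's controlled study condition:
54 electrodes on a 9×6 grid, 30 timesteps, 3 communities with activation
modes 0.9 / 0.6 / 0.3, stable over [0, 10) and [20, 30) and i.i.d.
uniformly random per electrode per timestep over [10, 20). The planted
partition splits electrodes as evenly as possible, contiguous in row-major
grid order (spatially coherent bands; switchable to a random even split).
The correlation network is materialized from labels by a two-level weight
model — 0.9 within a community, 0.05 between, plus symmetric Gaussian noise
(sd 0.02) truncated at zero — the minimal construction that makes the
planted structure cleanly detectable while leaving realistic resampling
ambiguity. During stable intervals each electrode's activation is exactly
its community's mode; during random intervals a uniformly drawn mode.
Everything is deterministic given the seed.

What the generator does *not* emulate: real ECoG weight distributions
(heavy tails, spatial autocorrelation of noise, volume conduction), slow
drift of community boundaries, and any waveform-level structure — passing
tests demonstrate the correctness of the pipeline's algorithms under a
known truth, not clinical performance. A seizure-like variant (a focal
community spreading at a fixed grid-distance rate with activation ramping
to 1) exists for demos and monotonicity checks only.

## Problem sizes and runtime

Default analysis conditions (54 electrodes × 30 timesteps, K ∈ [2, 8],
50 runs) run in ~15 s on one CPU. The larger-scale completion check uses
256 electrodes × 64 timesteps with a reduced consensus configuration
(K ∈ [2, 6], 15 runs) as its standing problem size, ~15 s. Enumeration in
the optimal matcher is capped at 10 clusters per side; beyond that the
solver engine applies.

## Known limitations

* Detection is per-timestep; there is no temporal smoothing (evolutionary
  clustering), so noisy timesteps can produce spurious short-lived
  communities that tracking then reports as births/deaths.
* Tracking is one-to-one: splits and merges appear as transition links, not
  as multi-assignments, and no event taxonomy beyond birth/death is mined.
* PAC's 0.1/0.9 cutoffs are conventional, not adaptive; extremely small
  electrode counts make the CDF statistics coarse.
* The barycenter objective is a surrogate for crossing count; orderings are
  near-optimal, not optimal.
* Raw-signal preprocessing (band extraction, artifact rejection,
  re-referencing) is explicitly out of scope; inputs are assumed clean.
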