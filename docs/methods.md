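# Methods

`hicfountains` detects and quantifies *fountains* — contact enrichments that
emanate from a single genomic locus and broaden with distance from the
diagonal of a Hi-C map — and simulates the loop-extrusion mechanism
proposed to create them: facilitated loading of cohesin at narrow platform
sites (enhancers), combined with desynchronized two-sided extrusion.

## Contact-map model

A `ContactMap` is one symmetric raw-count matrix per chromosome at a single
resolution; only cis contacts are modelled. Coordinates are 0-based
half-open and a position maps to bin `floor(pos / resolution)`.

**Balancing** is iterative correction to unit marginals. Bins with zero
coverage, or with coverage more than `mad_max` (default 5) median absolute
deviations below the median of nonzero bins, are excluded and carry NaN
weight. Convergence is reached when the largest relative marginal deviation
drops below `tol` (default 1e-5) within `max_iter = 200` sweeps; weights are
then rescaled so valid marginals equal 1. Note that iterative correction
forces equal marginals: applied to a matrix whose balanced form does not
have equal marginals (for instance a pure distance-decay map with edge
effects) it reshapes the decay near chromosome ends. This is inherent to
the normalization, not an implementation artifact.

**Expected and obs/exp.** The expected at separation *s* is the mean
balanced value over all valid bin pairs on that diagonal, per chromosome.
Obs/exp divides each balanced entry by the expected at its separation; bad
bins and zero/undefined expected give NaN. P(s) curves pool diagonal means
across chromosomes, weighted by valid-pair counts, into log-spaced bins
with ratio 2^(1/8); the log-derivative is a finite difference of log P vs
log s smoothed over 3 bins. NaN cells never propagate into any average
(count-weighted NaN-means throughout).

## Snipping and pileups

Windows are square and odd-sided: a "400 Kb window" at 10 Kb resolution is
±20 bins around the center bin (41×41), so the center is a unique cell on
the map diagonal. Out-of-chromosome cells are NaN. Pileups are per-cell
NaN-means with per-cell observation counts; coarse-graining takes NaN-means
over factor×factor blocks, truncating a trailing remainder.

## Fountain calling

The caller scores every diagonal window of the merged map against a
reference fountain mask and applies a threshold-and-filter pipeline.

* **Mask.** Either the NaN-mean of manually selected seed windows, or a
  synthetic binary wedge: cells within a given half-angle of the
  perpendicular bisector of the diagonal (both sides, so the mask is
  symmetric) beyond a minimum radius. Default synthetic mask: 30°
  half-angle, no inner cutoff.
* **Fountain score.** Pearson correlation between window and mask over
  jointly finite cells; NaN when fewer than 3 cells remain or either side
  is constant.
* **Noise score.** Scharr gradient magnitude (3×3 kernels with ±3/±10
  weights), averaged over interior cells, applied to the
  variance-stabilized raw-count window: bad bins are masked, counts are
  Anscombe-transformed (2√(k+3/8)), and the smooth component is removed
  with a 5-bin uniform filter. After stabilization the Poisson grain has
  unit amplitude in every window regardless of enrichment, so the score
  singles out genuinely sharp features — misassembly blocks, edges —
  rather than well-covered biological structure. (On plain obs/exp the
  *enriched* windows are the sharpest ones, because Poisson noise scales
  with the mean, and a top-quantile filter would preferentially delete true
  fountains.)
* **Peaks.** The score track is smoothed with a 3-bin moving average
  (adjacent windows share ~95% of their cells; without smoothing the track
  carries hundreds of micro local maxima of prominence ≲0.02 that poison
  threshold estimation), then local maxima are found with topographic
  prominence: peak height minus the higher of the two minima on the paths
  to the nearest higher points, with NaN gaps splitting the track into
  independent segments whose ends act as bases. Plateaus report their
  leftmost bin.
* **Prominence threshold.** Li's minimum cross-entropy threshold. The
  classic fixed-point iteration is run first, and the returned value is the
  exact global minimizer over all split midpoints (closed form via prefix
  sums), because the iteration can settle on a non-global fixed point for
  multimodal data. The threshold is estimated on the prominences of
  *replicate-supported* peaks (peaks with an Li-detected peak within
  ±20 Kb in every replicate): with single-map noise removed from the pool,
  the two-class split lands in the gap between reproducible signal and
  noise instead of inside the noise bulk.
* **Filters.** Candidates above the threshold are flagged (passed ⇔ no
  flag):
  - `badbin50`: center closer than 50 Kb to a bad bin;
  - `negative_corr`: negative mask correlation;
  - `replicate20`: not *detected* in every replicate — a replicate peak
    within ±20 Kb whose prominence clears 0.8× the final threshold (the
    factor allows for the √2-higher noise of half-depth replicate tracks);
  - `control_overlap`: re-detected at the same stringency within ±20 Kb on
    a control map, marking condition-independent features (putative
    rearrangements/misassembly);
  - `scharr_top25`: top 25% of the candidate set by noise score.
  Every filter is individually switchable and, apart from the quantile
  definition of `scharr_top25`, flags are assigned independently.

Output is a BED6+ table: chrom, start, end, name, fountain score, strand
(`.`), prominence, Scharr score, flags, passed.

### What the caller cannot do

All thresholds in the pipeline (Li, replicate re-detection, the Scharr
quantile) adapt to the data's own scale. On a dataset containing *no*
fountains at all, the strongest noise peaks still form a candidate set and
a fixed fraction of them survives every adaptive filter — at the default
fixture depth (5×10⁶ counts per 100 Mb) pure-noise windows reach wedge
correlations ≈0.25, overlapping the weak-fountain regime, and the caller
passes on the order of tens of calls per 100 Mb of pure noise. Rejecting
those would require an absolute significance gate that the pipeline
deliberately does not include. Interpret call lists accordingly: the
filters enforce reproducibility and artifact exclusion, not a
false-discovery-rate guarantee.

## Quantification

* **Protractor.** Each pileup cell is assigned an angle
  `atan2(|perp|, along)` ∈ [0°, 180°] about the center, where *along* is the
  component parallel to the diagonal and *perp* the distance from it; 90°
  is the perpendicular bisector where fountain signal concentrates. Sector
  means are NaN-means over cells with radius in `[r_min, r_max]` (defaults:
  10° sectors, r_min = 3 bins, r_max = window edge). Folding the
  half-planes makes the profile exactly invariant under transposition, and
  mirror-symmetric for bisector-symmetric input; boundary cells are
  assigned symmetrically about 90°, with exact-bisector cells contributing
  to both central sectors.
* **Differential classes.** Per fountain, DOWN if the mean score drops by
  more than `min_delta` (default 0.1 in correlation units) with all
  cross-replicate pairs agreeing in sign, UP symmetrically, else SAME. The
  published group sizes for the pioneer-factor triple knockout depend on
  unpublished thresholds and are not reproduction targets.
* **Enrichment.** Observed statistic: mean covered fraction of
  fountain-base bins by an element class. Null: the fountains re-placed
  uniformly over valid bins (per-chromosome counts preserved) `n_rand`
  times; z-score and one-sided p from a normal fit to the null,
  Benjamini–Hochberg FDR across element classes.

## Extrusion simulation

1D stochastic lattice, 1 site = 1 Kb, periodic. Extruders occupy two leg
sites; each step is unload → load → step:

1. every extruder unloads with probability `p_unload`;
2. every empty adjacent site pair loads a new extruder with probability
   `p_load`, multiplied by the enrichment factor `E` when the pair touches
   a 1-site platform (mechanisms with platform-only loading skip the
   background term);
3. legs step one site outward; a leg whose target site is occupied by any
   leg never moves while its partner still may. Simultaneous moves are
   resolved in order of increasing lattice site with occupancy re-checked,
   so legs can never cross or share a site.

Mechanisms: `background` (extruders also load everywhere and collide with
platform-loaded ones), `barriers` (platform-only loading; every site within
±50 Kb of a platform is a candidate barrier that stalls a crossing attempt
with probability `p_stall`, memorylessly), `decoupled` (platform-only
loading; each leg steps independently with probability `p_step`). The
synchronized hairpin control is `barriers` with `p_stall = 0`.

Defaults encode the best-fit regime: L = 2500 sites (2.5 Mb), platforms
every 500 Kb, E = 10, processivity 2·p_step/p_unload = 150 Kb
(p_unload = 1/75), and p_load = p_unload/150 so the background density
balances to one extruder per 150 Kb. With per-pair loading these three
constraints fully determine the model; the steady number of
platform-origin extruders per platform is then 2·E·p_load/p_unload =
2·10/150 ≈ 0.13 — an identity of the model class, independent of the
unloading rate.

**Occupancy.** Per-site leg counts averaged over every post-burn-in step,
re-centered and averaged over platforms. The peak width (FWHM, Kb) is
measured on a 5-site-smoothed profile: background level from offsets
150–240 Kb on both sides, peak height as the maximum above background near
the center, and the width between the *outermost* half-maximum crossings
scanning inward from the background zone (the top of the peak is
structured because legs vacate the loading site at one site per step).

**Contact reconstruction.** Instead of 3D polymer dynamics, contacts come
from an analytic Gaussian-chain kernel:
`P(i,j) ∝ (d_eff(i,j) + 1)^(-3/2)` with `d_eff` the exact shortest path
through the chain backbone (unit edges, periodic) plus zero-length bridges
at each extruder's leg pair. Shortest paths are computed by min-plus
composition through the small set of bridge endpoints (Floyd–Warshall on
the endpoint graph), which is exact and fast. This preserves the geometry
extrusion imprints on the map — hairpins, fountains, loop shoulders — at a
desk scale; it does not model excluded volume, compartmental affinities, or
finite chain relaxation. One consequence worth noting: *any* loop pinches
together the region beyond its two legs, so a synchronized hairpin also
produces a broad low plateau in every cross-section. The cross-section
width statistic therefore measures the *ridge* — the extent of the
transverse profile above half its peak enrichment — which stays flat for
hairpins and broadens for desynchronized mechanisms. The broadening is
measured over heights up to ~75 Kb from the base; beyond the processivity
reach the enrichment cone fades and the surviving far contacts come from
the rare uncollided (hence more synchronized) extruders.

**Pileups and fit.** The published pipeline is followed: 200 Kb windows at
platforms, normalized by expected, coarse-grained by 10 to 10 Kb bins
(20×20). Two routes exist: the full-lattice obs/exp
(`simulated_average_fountain`) and a window-restricted kernel normalized by
the window's own per-separation mean (`platform_window_pileup`), which
converges much faster when background loops dominate the ensemble and is
the default for parameter sweeps. Goodness of fit: mean squared difference
of protractor profiles plus Spearman correlation of off-diagonal pileup
cells; sweeps return one row per grid point sorted by protractor MSE.

## Synthetic fixtures

The generator emulates exactly the statistical structure the caller relies
on: a power-law distance decay `(s+1)^exponent` (default −1.5);
multiplicative wedge enrichments so obs/exp inside a fountain has a
constant target level of `1 + strength`, with cosine tapers at the angular
edge and the outer 20% of the radial extent and an onset ramp over the
first ~8 bins of radius (fountains are pinched near the diagonal);
misassembly-like artifacts — sharp square diagonal blocks implanted in
every map including a fountain-free control, giving the noise-score and
control filters their intended prey; independent Poisson counts per
replicate at fixed total coverage; and shared bad bins. Everything is a
deterministic function of the seed. The standard fixture is 100 Mb in
4×25 Mb chromosomes at 10 Kb bins, 20 fountains of strength 1.0 (30°
half-angle, 200 Kb extent), ~20 artifacts, 1% bad bins, 5×10⁶ counts per
replicate, two replicates plus a control.

What the fixtures do *not* emulate: compartments, TADs, trans contacts,
coverage heterogeneity along the genome, or replicate-specific biases.
Passing tests therefore demonstrate the pipeline's behavior under its own
statistical assumptions, not performance on real embryonic Hi-C.

Call evaluation matches calls to truth greedily, closest first, one-to-one
within a bin tolerance; precision is matched/called (NaN when nothing is
called) and recall matched/truth.

## Problem sizes

The suite and the reproduction script run at desk scale by choice: the
steady-state simulation uses the full 2.5 Mb default lattice with ~2×10⁶
steps; mechanism comparisons use a 400 Kb lattice with one platform and
20 seeds; sweeps use the default lattice with ~3×10⁴ sampled steps per
grid point; caller fixtures are the standard 100 Mb recipe.

## Known limitations

* The contact kernel is an equilibrium Gaussian-chain approximation; it
  cannot reproduce quantities that depend on 3D density, chain relaxation
  times, or excluded volume.
* The caller's thresholds are adaptive (see above): there is no absolute
  false-positive guarantee on fountain-free data.
* Iterative correction on short chromosomes distorts the distance decay
  near the edges; expected profiles at separations comparable to the
  chromosome length rest on very few pairs.
* The replicate filter assumes replicates share the fountain signal and
  differ by independent counting noise; batch-correlated artifacts will
  survive it (that is what the control filter is for).
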