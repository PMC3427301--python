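# Methods

## The problem

When habitat fragmentation reaches its late stage, total habitat area and the
number of habitat patches decline together as whole patches are eliminated.
The species–area relationship (SAR), S = cA^z, is the standard description of
how richness S responds to habitat amount A; its exponent z measures the
sensitivity of richness to area. `fragsar` analyses the *landscape-scale* SAR
(LSAR): each data point is an entire landscape (a set of habitat patches),
with S the pooled richness of all member patches and A their summed area.
Watching how the LSAR z changes as patch number falls separates the effect of
losing area from the effect of fragmentation *per se* — the change in spatial
configuration (patch number PN, patch size variability PSV, shape complexity
LSI, isolation MDM) at a given amount of habitat.

## Pipeline

1. **Input system.** 152 islands (area ha, perimeter m, mainland distance m)
   and a 383-species presence/absence matrix, either read from CSV or drawn
   from the synthetic generator below. Species on ≤10% of islands
   (floor(0.10·N) = 15 of 152) are "rare", the rest "common".
2. **Simulated landscapes.** For every patch number pn in 2..50, island
   subsets of size pn are drawn uniformly without replacement, stratified so
   their total areas spread evenly over five equal-width sections of the
   admissible range [sum of the 50 smallest areas, sum of the 2 largest];
   200 replicates per (pn, section) cell gives 49 × 5 × 200 = 49,000
   landscapes.
3. **Incidence views.** Pooled richness of each landscape is computed under
   the observed matrix, its rare-only and common-only restrictions, and two
   nulls that keep each island's richness S_i but randomize species identity:
   RDM (uniform draws without replacement) and OWRDM (draws weighted by
   observed occupancy).
4. **z-series.** Per patch-number level, OLS of log10(richness) on
   log10(total area) over the 1,000 landscapes of that level (sections
   pooled) gives one z per level per view. Null views average z over
   randomized replicates (default 100) and report the replicate SD.
5. **Threshold.** A continuous two-segment ("broken stick") regression of z
   against pn locates the breakpoint ψ separating the responsive phase
   (pn < ψ, z rising steeply as patches are lost) from the stable phase
   (pn ≥ ψ, z nearly flat).
6. **Attribution.** Spearman and partial Spearman rank correlations relate
   attributes to richness and z (each landscape inheriting its level's z),
   and adjusted-R² variation partitioning splits the variance of z between
   total area and the fragmentation set {PN, PSV, LSI, MDM} within each
   phase.

## Synthetic archipelago

The generator emulates a subtropical reservoir land-bridge system surveyed
for vascular plants; it is the test bed for every downstream stage.

* **Areas**: log-normal, ln-mean 0.3, ln-sd 2.1, truncated to [0.25, 260] ha
  (inverse-CDF sampling). This gives a median island near 1.4 ha and about
  three islands per 152 above 100 ha. The 260 ha cap reflects the surveyed
  system, whose two largest islands sum to ≈259 ha; a handful of comparably
  large islands at the top of the range is a real feature of that system and
  a structural requirement of the stratified sampler (2-patch landscapes
  must be able to reach every area section — a single dominant outlier
  island would leave mid-range sections unreachable).
* **Perimeters**: equal-area-circle perimeter times a log-normal inflation
  factor (ln-mean 0.15, ln-sd 0.10, lower-truncated at 1), so every island
  respects the isoperimetric bound and single-island LSI ≈ 1.1–1.3.
* **Mainland distances**: uniform on [0, 3000] m — a scalar attribute; no
  explicit map.
* **Incidence**: species j occupies island i with probability
  logistic(logit(w_j) + b·(log10 A_i − mean log10 A)). Target occupancies
  w_j are log-normal (ln-mean −2.80, ln-sd 1.20, the `occupancy_shape`),
  chosen so ~2/3 of the pool falls below the 10% rare cutoff, matching the
  observed 254/383 split; a log-series alternative would also be defensible
  but the log-normal keeps one interpretable spread parameter. Centering on
  the mean log-area keeps realized occupancy near w_j for any b. The single
  coefficient b is calibrated by bisection on [0, 5] (tolerance 0.01) so the
  patch-scale SAR slope matches `z_patch` = 0.16; calibration uses a seeded
  1,000-island archipelago and expected (not sampled) richness, making the
  objective smooth and monotone. Empty islands/never-present species get one
  uniformly placed presence — the minimal patch-up preserving the matrix
  invariants.

What the generator does *not* emulate: spatial autocorrelation between
islands, species co-occurrence structure beyond the shared area response,
nestedness from ordered colonization/extinction, and any habitat
heterogeneity within islands. Tests passing on this system show the
machinery is correct and that the qualitative fragmentation signatures
(null-z collapse, threshold in z, dominance of fragmentation *per se* in the
responsive phase) emerge from area-structured occupancy alone; they do not
certify effect sizes on real survey data.

## Numerical and design choices

* **Stratified sampling mechanism.** Batched uniform rejection (4,096 draws
  per batch, shared across the five sections of a pn level) is the primary
  mechanism; its acceptance distribution is uniform over qualifying subsets.
  Cells whose qualifying subsets are vanishingly rare under uniform draws —
  notably the lowest-area section at high pn, which is essentially "the pn
  smallest islands" — fall back to a swap-chain MCMC: from a feasible subset
  (found by a multi-start randomized hill climb on the distance to the area
  interval), propose swapping one member for one non-member, both uniform,
  and accept iff the total stays in bounds. The proposal is symmetric, so
  the stationary distribution is uniform over the qualifying subsets of the
  chain's connected component; draws are taken after 500 burn-in swaps with
  thinning 100. Provably impossible cells (pn smallest islands already above
  the section, or pn largest below it) raise an error naming the cell, or
  are skipped on request.
* **Sections** are equal-width on the arithmetic area scale; a boundary
  value belongs to the lower section except the global maximum.
* **PSV** is the sample (n−1) coefficient of variation reported as a ratio;
  any fixed convention leaves the rank-based analyses unchanged. PSV of a
  single-patch landscape is 0.
* **LSI** divides total edge E (m) by the perimeter of the one circle whose
  area equals the landscape total (ha converted ×10⁴ inside the ratio), so
  LSI ≥ 1 always and equals √pn for pn equal circular islands.
* **MDM** is the unweighted mean of member islands' mainland distances.
* **LSAR fits** use log base 10; zero-richness landscapes (possible under
  the rare-species view) are excluded from the log fit with a recorded
  count rather than offset-corrected, since +1 offsets bias z.
* **Breakpoint**: profiled SSE over ψ on a 0.1 grid spanning the interior
  x-range, then golden-section refinement in the bracketing interval; the
  linear coefficients are OLS at each candidate. The overall p-value is an
  F-test of the fitted broken stick against the intercept-only model with
  3 model df (ψ counted as a parameter). Fits improving SSE over a single
  line by <1% are flagged `no_threshold`; constant series return a slope-0
  fit with undefined ψ. An integer-valued ψ assigns its own level to the
  stable phase (pn ≥ ψ), with a 1e-6 tolerance against float jitter.
* **OWRDM draws** use exponential race keys (Exp(1)/w per species, keep the
  S_i smallest), which is exactly the successive-renormalized weighted draw
  without replacement, vectorized. With equal weights it reduces to RDM.
  A species may be absent from a single null replicate; null matrices
  therefore relax the every-species-occurs-somewhere invariant.
* **Partial Spearman** midranks all columns, then correlates OLS residuals
  of x and y on the controls; p from the t approximation with
  df = n − 2 − |controls|. Bonferroni families: all pairs for the
  correlation matrix, all tests sharing one control set for the partial
  tables.
* **Variation partitioning** uses Ezekiel adjusted R² on raw (not ranked)
  values, as redundancy analysis is linear; negative fractions are reported
  as computed. With a univariate response the RDA reduction to OLS is exact
  (cross-checked against vegan::varpart in the test suite). A phase whose z
  is constant (e.g. a single pn level) returns fractions (0, 0, 0, 1).
* **Seeding**: the pipeline derives per-stage seeds from the global seed by
  hashing the stage name, so adding or removing a view never perturbs the
  draws of another stage.

## Problem sizes

The default study-scale configuration (152 islands, 383 species, 49,000
landscapes, 100 null replicates per null model) runs the whole pipeline in
well under two minutes on one core; the test suite uses the same scale for
the end-to-end checks and smaller systems (12–40 islands) for unit tests.
The reproduction script (`scripts/acceptance.py`) uses the full default
configuration.

## Limitations

* Landscapes are independent draws, not a nested fragmentation trajectory;
  this matches the resampling design being reproduced but means consecutive
  pn levels share no patches.
* The breakpoint model allows exactly one threshold; richness series with
  other shapes (the "hockey stick" of common species) are not separately
  fitted.
* The swap-chain fallback guarantees in-bounds draws but, unlike rejection,
  successive draws within a cell are weakly autocorrelated (thinning 100
  swaps keeps this negligible at the default scales).
* Feasibility detection is heuristic beyond the provable min/max bounds: a
  cell can in principle be declared infeasible after the multi-start search
  fails, although no such case arises at the default configuration.
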