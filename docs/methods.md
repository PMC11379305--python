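# Methods

## The assessment problem

`veldscore` implements the quantitative chain of a rangeland (veld) condition
assessment as practised in southern African grassland ecology. The field
protocol is a point-to-tuft transect: a thin rod is lowered to the ground at
1-m intervals along a 50-m line, and each point records either a direct
strike on a grass tuft (with the tuft's longest and shortest basal axes, in
cm), a bare-ground point within 40 cm of a tuft (with the distance and the
nearest species), or a wide bare patch (bare ground more than 40 cm across,
with no species). The surveyed design the package emulates is 15 such
transects in each of three topographic locations — open grassland plains,
stream terraces and upland slopes — giving 45 sites of 50 points.

From those records the pipeline computes, per transect and per location:

1. **Basal cover** from the published regression
   `BC = 19.8 + 0.39 D − 11.87 ln D + 0.64 d + 2.93 ln d`, where `D` is the
   transect mean point-to-nearest-tuft distance (cm) and `d` the transect
   mean basal tuft diameter (cm).
2. **Diversity**: richness, Shannon–Wiener `H′ = −Σ pᵢ ln pᵢ` (nats),
   Simpson dominance `D = Σ pᵢ²`, and Pielou evenness `E = H′ / ln S`.
3. **Condition and grazing capacity**: per-species condition score =
   occurrences × forage factor; veld condition % relative to a benchmark;
   grazing capacity `GC = −0.03 + 0.00289 X₁ + (X₂ − 419.7) × 0.000633`
   in large stock units (LSU) per hectare, with `X₁` the veld condition %
   and `X₂` mean annual rainfall (mm, default 661).
4. **Composition statistics**: Bray–Curtis dissimilarities between sites,
   the ANOSIM permutation test across locations, and SIMPER decomposition of
   between-location dissimilarity into species contributions.
5. **Woody layer**: point-centred quarter (PCQ) tree density
   (`10000 / r̄²` trees ha⁻¹ from the mean quarter distance `r̄` in m) and
   height-class frequencies (<1 m, 1–2 m, >2 m; half-open, lower-inclusive).

## Conventions and numerical choices

- **Occurrence definition.** Both tuft hits and near-bare records (the
  nearest species to a bare point) count as species occurrences; bare
  patches count toward the bare fraction only. `to_abundance_matrix` takes a
  `count_bare_near` flag for the hits-only alternative. Under this
  definition every point either names exactly one species or is a bare
  patch, so species encounter rates plus the bare-patch percentage total
  100% — an identity the tests exploit.
- **Tuft diameter** is the arithmetic mean of the longest and shortest basal
  axes. The field protocol measures both axes without stating a combination
  rule; the arithmetic mean is the simplest unbiased convention, and any
  alternative (e.g. geometric mean) would differ by under 3% at the
  asymmetries the generator produces.
- **Basal-cover aggregation.** The regression is defined on transect-level
  means, so it is applied once per transect, not per point. Tuft hits
  contribute distance 0 to the `D` mean; bare patches are excluded from it.
  `D` is floored at 0.1 cm so `ln D` stays defined on all-hit transects, and
  the regression output is clamped to [0, 100] % with a warning (the linear
  form goes negative around `D` ≳ 20–30 cm with small tufts, and exceeds
  100 at the floor with large tufts). Below the clamp the regression is
  strictly decreasing in `D` for `D` < 30.4 cm (∂BC/∂D = 0.39 − 11.87/D).
- **Simpson's index** is reported as dominance `Σ pᵢ²`, not complement
  `1 − Σ pᵢ²`: published per-site values of ~0.3 alongside `H′` ≈ 1.4 are
  only consistent with the dominance form. Natural logarithms are used
  throughout (the evenness definition forces `ln`; `H′` follows). No
  small-sample bias corrections are applied — these are plug-in estimators.
- **Veld condition benchmark.** The benchmark total against which a
  transect's summed condition score is expressed is `n_points × 10` (a
  transect hitting a forage-factor-10 species at every point). The method
  this normalisation stands in for uses an externally published benchmark
  sward that is not reproducible from its description; the divisor is
  therefore configurable (`benchmark_factor`). Non-grass species carry
  forage factor 0 in scoring unless a factor is supplied.
- **Grazing capacity** is floored at 0 LSU ha⁻¹ with a warning (the linear
  model goes negative for poor veld at low rainfall); the reciprocal
  ha LSU⁻¹ — the unit in which stocking advice is usually phrased — is
  reported only when capacity is positive. Both unit conventions are always
  emitted because an "8% lower capacity" claim inverts between them.
- **ANOSIM.** `R = (r̄_between − r̄_within) / (M/2)` on the ranks of all
  `M = n(n−1)/2` pairwise Bray–Curtis dissimilarities, average ranks on
  ties. Significance is by label permutation: exact enumeration of all
  distinct label assignments when there are ≤ 10,000 of them, otherwise
  Monte-Carlo with the +1/+1 rule `p = (1 + #{R* ≥ R}) / (1 + n_perm)`
  (the observed labelling counts itself, so p is never 0). The default is
  999 permutations, seedable. Constant dissimilarity matrices return R = 0,
  p = 1 with a warning.
- **SIMPER** follows Clarke's decomposition: for each between-group site
  pair, species *i* contributes `|xᵢ − yᵢ| / (Σx + Σy)`, which sums exactly
  to that pair's Bray–Curtis value; contributions are averaged over all
  between-group pairs and reported pairwise per group pair (no pooled
  multi-group decomposition). Ordination (NMDS) is deliberately not
  implemented; the statistical chain runs directly on the dissimilarities.
- **Collinearity screen** (for soil/environment variable tables): greedy —
  for each variable pair with |Pearson r| above the threshold (default
  0.96), the later-listed variable is dropped in favour of the earlier;
  zero-variance variables are excluded from the correlations with a warning
  but retained.
- **PCQ density** uses the standard Cottam–Curtis estimator
  `10000 / r̄²`. Note that published mean tree distances of ~5 m paired with
  densities of ~6000–7500 trees ha⁻¹ are mutually inconsistent under this
  (or any standard plotless) estimator, which gives ~400 trees ha⁻¹ at
  those distances; the package documents and uses the standard estimator
  rather than reverse-engineering an unstated one.

## The synthetic generator

No field data are deposited with the survey this package's analysis chain
reproduces, so `synthetic_data` generates surveys with the structure the
analysis assumes. Per location it takes a species relative-abundance
simplex, nominal bare-near and bare-patch probabilities, a log-normal tuft
basal diameter (cm) and a log-normal bare-point distance (cm). Each point
independently draws an outcome category; species-naming points draw a
species from the simplex; tuft axes are drawn as `(m + |δ|, m − |δ|)` around
the log-normal diameter `m` with half-normal asymmetry `δ` (so longest ≥
shortest by construction); bare distances beyond 40 cm are re-coded as wide
bare patches, exactly as the 40 cm field rule dictates. The re-coding is
species-independent, so the species composition of naming points is exactly
the specified simplex — which is what the binomial recovery tests check.

`paper_like_scenario()` is the default design: 15 sites × 50 points per
location; species pools of 22/19/16 for plains/streams/uplands; an
*Aristida*-like increaser III dominant at 0.34 relative abundance in plains
and a *Sporobolus*-like one at 0.29 in streams; all four decreaser grasses
confined to the plains (the *Themeda*-like decreaser at 0.019); the woody
encroacher present only in streams and uplands. Forage factors are
synthetic but field-plausible (palatable decreasers 7–10, wiry increaser III
grasses 1–2, forbs and woody plants 0). The nominal outcome probabilities
(0.80 hit / 0.16 bare-near / 0.04 bare-patch) and log-normal parameters
(tuft diameter median 8 cm, σ = 0.4; bare distance median 12 cm, σ = 0.6)
are modelling choices at field-realistic magnitudes for dense tussock
grassland; all are user-substitutable. `paper_like_pcq_scenario()` puts 68%
of stream-site trees and 49% of upland trees below 1 m, matching the
reported height structure of the encroacher.

What the generator does *not* emulate: spatial autocorrelation along
transects (points are i.i.d.), between-site heterogeneity within a location
beyond sampling noise, multi-season dynamics, and grazing feedback. Tests
passing on this generator therefore demonstrate correctness of the
computational chain and its statistical calibration under idealised
sampling, not ecological validity on real transects.

## What the tests establish

- The two published regressions are reproduced against independent
  re-typings to 1e-9 over their input ranges, with spot checks at the
  printed precision (BC(1,1) = 20.83; GC(50, 661) = 0.26724 LSU ha⁻¹).
- ANOSIM's Monte-Carlo p agrees with brute-force enumeration of all label
  assignments within two Monte-Carlo standard errors on every two-group
  design of ≤ 8 sites, and the R statistic matches scikit-bio's
  implementation exactly; the test is invariant under strictly monotone
  transforms of the dissimilarities, as a rank-based test must be.
- SIMPER contributions reconstruct the pairwise and mean between-group
  Bray–Curtis values to 1e-9 on random matrices.
- On the default scenario, generated encounter frequencies sit inside exact
  binomial 95% confidence intervals of the specified abundances for ≥ 95% of
  species; ANOSIM across locations rejects at p < 0.05 in ≥ 90% of 100
  replicates, and under an identical-composition null its rejection rate
  over 200 replicates stays within 5% ± 3% (the permutation test is
  slightly conservative by construction of the +1/+1 rule). Replicated
  runs use 199 permutations per test — the smallest count that resolves
  p < 0.05 comfortably — to keep the replicate studies quick; one-off
  analyses default to 999.

## Known limitations

- The veld-condition benchmark is a convention, not the cited method's
  benchmark sward; absolute veld condition percentages (and hence grazing
  capacities) are comparable within analyses using the same benchmark only.
- The PCQ density estimator cannot reproduce the published density figures
  (see above); the discrepancy is documented rather than resolved.
- Statistical hypothesis testing outside the compositional chain
  (Kruskal–Wallis, ANOVA and relatives on diversity or scores) is out of
  scope — standard tests that belong to a general statistics library.
- Simpson/Shannon values are plug-in estimates; at 50 points per transect
  the downward bias of plug-in `H′` is roughly `(S−1)/(2n)` ≈ 0.1 nat and
  is not corrected, matching common field practice.
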