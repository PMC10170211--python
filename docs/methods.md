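# Methods

`betachron` asks a comparative question about community time series: do
assemblages that contain naturalized alien species show elevated short-term
compositional change relative to assemblages where aliens have never been
recorded?  This note describes the statistical machinery, the synthetic
data generator used to exercise it, and the design decisions taken where
more than one defensible convention exists.

## Data model and curation

The unit of analysis is the *assemblage*: one monitoring study at one
georeferenced location, holding long-format records (year, plot, species,
abundance).  Curation proceeds in a fixed order:

1. **Ingestion** — zero-abundance rows are dropped; negative or
   non-numeric abundances and within-study coordinate inconsistencies are
   hard errors.  Column names are configurable through a dialect map.
2. **Name standardization** — a user-supplied synonym table maps raw to
   accepted names; records of synonyms collapsing to one accepted name
   within a (year, plot) are merged by summing abundance.  Standardization
   is deliberately table-driven — no live taxonomic-backbone queries — so
   runs are reproducible offline.  Unmatched names pass through and are
   reported, not rejected: a name absent from the table is still a valid
   observation.
3. **Alien status** — a study is flagged invaded iff any species recorded
   at *any* census is listed for the study's region in a region-keyed
   checklist of naturalized aliens.  Status is study-level and constant
   over the series.  One region per study is assumed.
4. **Selection** — studies censused in fewer than 3 distinct years are
   excluded (census years need not be consecutive calendar years).

## Effort equalization

Sampling effort (number of plots) often varies among years, and richness
and dissimilarity metrics respond to effort.  Before any metric is
computed, each study whose effort varies is rarefied: in every year a
uniform random subset of plots of size equal to the minimum yearly effort
is retained.  The sampling unit is the plot, not the record.
Constant-effort studies pass through untouched and consume no randomness.
One draw per study is the default (the seed is recorded in the run
manifest); `rarefy_reps > 1` averages the per-assemblage medians over
independent draws for sensitivity analysis, since a single draw carries
sampling variance of its own.

## Dissimilarity partition

For two presence/absence censuses with `a` shared species, `b` unique to
the earlier and `c` unique to the later census:

    beta_jac = (b + c) / (a + b + c)
    beta_jtu = 2 min(b, c) / (a + 2 min(b, c))
    beta_jne = beta_jac - beta_jtu

`beta_jtu` is replacement-only dissimilarity (insensitive to richness
difference); `beta_jne` is the richness-driven, nestedness-resultant
remainder.  When `min(b, c) = 0` one census is a subset of the other and
turnover is defined as zero, so the whole dissimilarity is nestedness;
this also covers the degenerate one-empty-census case.  Comparisons are
made between *consecutive censuses* — adjacent entries of the observed
year sequence, which may span calendar gaps; the gap is recorded per pair
so users can filter or normalize, but dissimilarities are not divided by
interval length by default.  Each assemblage is summarized by the median
of each component over its pairs (midpoint convention for even counts).

## Richness and rank change

* `median_richness`: median over censuses of per-census richness.
* `richness_difference`: (S_later − S_earlier) / S_union.  The union
  denominator guarantees the value lies in [−1, 1], equals 0 for
  equal-richness pairs and is antisymmetric.  A variant dividing by the
  *shared* count is available (`denominator="shared"`) but is unbounded
  (e.g. 3 vs 1 species with 1 shared gives −2) and undefined for disjoint
  pairs, which is why it is not the default.
* `rank_difference`: mean over the union of |Δ relative rank|.  Within a
  census, present species are ranked by descending abundance with average
  ranks for ties; species absent from one census share the tied rank
  `S_present + (S_union − S_present + 1)/2`; ranks are divided by the
  union size.  The metric is symmetric, scale-free (invariant to positive
  rescaling of either census) and zero iff species sets and rank orders
  coincide.  Tie- and absence-handling conventions differ between
  published rank-abundance-difference implementations; the convention
  above is fixed, documented, and covered by an independent brute-force
  rank assigner in the test suite.

## Group-level inference

Each retained assemblage contributes one summary row.  The group contrast
for each metric is a Gaussian GLM (identity link), equivalently OLS:

    metric ~ intercept + alien_flag + latitude + longitude

with two-sided t tests per term.  Coordinates enter as fixed covariates to
absorb broad geographic trends; a true mixed-effects or spatially explicit
error model is out of scope.  Responses are modeled untransformed, including
the [0, 1]-bounded dissimilarity medians.  Spatial structure is screened
rather than modeled:

* **Moran's I** with inverse great-circle-distance weights (haversine,
  Earth radius 6371 km), zero diagonal, expectation −1/(n−1) and the
  randomization (kurtosis-corrected) variance with a two-sided normal
  approximation.  Coincident distinct sites receive the largest finite
  weight observed, with a warning.  Row standardization is available but
  off by default; the implementation with row standardization on agrees
  with the R `ape` reference to 1e−9 (cross-checked in the test suite).
  The weight scheme is configurable because inverse distance, while
  conventional, is a choice.
* **Distance decay**: pairwise |metric difference| against great-circle
  distance, summarized by Spearman's rho.
* **Acceleration**: per assemblage with at least four census years, the
  Spearman correlation of pair dissimilarity with the pair's later census
  year; fewer than four years yields an explicit not-applicable marker.
  Degenerate inputs (constant values) report NaN with a warning instead of
  failing.

A `--period` window recomputes all summaries on censuses inside the window
(studies falling under 3 censuses within the window are dropped and
logged), mirroring recent-period sensitivity analyses.

## Synthetic community generator

The generator emulates the structure of multi-plot vegetation monitoring
data so the full pipeline is testable without any external database:
studies with 3–41 possible census years, per-year plot counts varying
within a range, lognormal species abundances, georeferenced study
locations, and a region-keyed alien checklist that exactly matches the
simulated corpus.

Change is injected through three separately controlled channels:

* **Composition.** Each census every resident species goes locally extinct
  with probability `extinction_rate` (group-specific) and a Poisson number
  of species immigrate from the pool — immigration/extinction balance in
  the island-biogeography sense.  By default the immigration intensity is
  `extinction_rate × target_richness`, which makes richness mean-reverting
  to its starting value in *both* groups while the replacement *rate*
  scales with the extinction rate.  This is what lets an
  elevated-turnover group show higher Jaccard/turnover with no systematic
  richness difference.  Supplying an explicit `immigration_rate` gives a
  constant-intensity variant instead (richness then equilibrates at
  `immigration_rate / extinction_rate`).
* **Rank shuffling.** Per census, the abundance multiset of the resident
  community is held fixed and dealt out to species in the order of a noisy
  score (`mu_species + Normal(0, rank_noise)`); larger `rank_noise` means
  stronger rank churn with an unchanged abundance distribution.  Only
  species whose baseline abundance is at least `rank_shuffle_floor`
  (default 8 individuals) take part.  This floor exists because species
  near abundance 1 are sometimes lost by plot subsampling during
  rarefaction: if rank churn rotated species through those barely
  detectable slots, a rank-noise difference between groups would leak into
  apparent presence/absence change.  Restricting the shuffle to
  comfortably detectable species keeps the rank channel orthogonal to the
  beta channel, which is the stated purpose of having separate knobs.
  An independent log-abundance jitter (the more obvious design) was
  rejected for the same reason: it changes the rare tail of the abundance
  distribution and hence detectability itself.
* **Alien presence.** Every study carries `n_aliens` rare "injected"
  species persisting through the series at a small total relative
  abundance (`alien_rel_abundance`, default 3%, reflecting that aliens are
  typically rare in invaded assemblages).  In invaded studies they come
  from the alien pool; in uninvaded studies, from the native pool.  Both
  groups therefore share identical community structure — same expected
  richness, same abundance distribution, same dynamics — and differ only
  in whether the rare members carry the alien label.  This construction is
  what makes the alien label metric-neutral under matched dynamic rates,
  so type-I calibration of the group model can be tested meaningfully.
  (An earlier design with aliens only in invaded studies biases beta
  *downward* there, because persistent aliens are extra never-turning-over
  shared species.)

Default scenario (chosen to represent a realistic mid-sized monitoring
corpus): 20 invaded + 20 uninvaded studies, species pool 200, initial
richness 30, 10 annual censuses, 3–6 plots per year, extinction 0.30
(invaded) vs 0.15 (uninvaded) per species per census, abundances
lognormal(2, 1), coordinates uniform in a lat [−40, 60] × lon [−120, 150]
box, one region.  Each study has its own RNG stream derived from
(seed, study index), so any study is reproducible in isolation and output
CSVs are byte-identical across runs with the same seed.

What the generator does **not** emulate: real spatial structure (locations
are uniform, so spatial-autocorrelation screens are expected to be null),
dispersal limitation, interspecific interactions, observer error in
identification, multi-region studies, and trends in alien abundance over
time.  Passing recovery tests therefore shows the pipeline detects the
modeled contrast at realistic sizes and holds its error rate under the
modeled null — not that real invaded floras behave like the model.

## Monte-Carlo evaluation

Three standing scenarios drive calibration and power checks
(`betachron.montecarlo`), each replicate simulating a full corpus and
running the complete pipeline:

* **headline** — elevated extinction in the invaded group: the alien term
  should be detected for median Jaccard and turnover (positive, p < 0.05)
  in ≥ 90% of replicates, while median richness rejects at its nominal 5%.
* **rank channel** — matched extinction, elevated `rank_noise` (1.5 vs
  0.25) in the invaded group only: median rank difference responds, median
  Jaccard stays at nominal rejection.
* **null** — identical generating parameters in both groups (aliens still
  present, dynamically neutral): the alien term's rejection rate should
  sit at the nominal level.

The test suite runs these at 100, 100 and 400 replicates respectively of
the default 40-study, 10-census corpus; the full suite completes in a few
minutes on one core.

## Numerical conventions and degenerate inputs

* Medians use the midpoint convention for even counts.
* Presence means abundance > 0 after rarefaction; no minimum-abundance
  cutoff.
* Comparisons of two empty censuses, Moran's I on constant values or
  fewer than 3 sites, and group models with fewer than 2 assemblages per
  group raise typed errors; the pipeline records such cases as annotated
  NaN rows rather than aborting a whole run.
* Rank-deficient group-model designs raise an error naming the collinear
  column.
* All randomness flows from one integer seed; rarefaction streams are
  additionally keyed by study id so results do not depend on processing
  order.

## Known limitations

* The group model ignores residual spatial correlation beyond the two
  coordinate covariates; Moran's I screening is diagnostic, not corrective.
* Dissimilarity responses are treated as Gaussian; with medians over ≥ 2
  pairs on [0, 1] this is adequate for contrast testing but not for
  prediction intervals.
* No multiple-testing correction is applied across the six response
  metrics.
* Alien status is binary presence on a checklist; propagule pressure,
  residence time and abundance of aliens are not modeled.
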