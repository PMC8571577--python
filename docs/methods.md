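# Methods

This note documents the models and procedures implemented in
`recruits`, the defaults they ship with, and the choices made where the
design was genuinely open.

## Recruit cohorts

A tree is *recruited* at observation time *T* (years since disturbance)
when it is at or above the 10 cm DBH census threshold at *T* and was
below it — or absent, never having reached the threshold — one census
interval (2 years) earlier. "Above 10 cm" includes the boundary tree
(≥ 10.0 cm), the usual census convention; the threshold is a parameter.
Since sub-threshold trees are not inventoried, recruitment is anchored
at a tree's *first* census at or above the threshold; a tree later
shrinking below the threshold is not re-recruited. Trees already at the
threshold at the last census before disturbance (survivors) belong to
no cohort. Observation starts at year 5, when disturbance-induced
mortality is assumed over, and proceeds at 2-year steps to year 29;
control plots use the same calendar start. Because disturbance kills
trees in the disturbance year itself, "the last census before
disturbance" is the year −1 census. Census gaps inside the analysis
window raise an error rather than being interpolated: the method
assumes annual censuses, and silent interpolation would corrupt the
crossing rule.

## Taxonomic uncertainty

Vernacular names map probabilistically onto botanical species. The
association probability α(v, s) is estimated as the fraction of
records carrying vernacular *v* whose species was botanically resolved
to *s*, pooled over all plots and censuses (the record-level pooling
follows the estimator's definition; per-campaign estimation is not
implemented). Unresolved trees are completed by a categorical draw from
their vernacular's α-vector — once per *tree*, not per record, because
a tree cannot change species between censuses. Repeating the resolution
(100 iterations by default) and recomputing every downstream metric
yields an ensemble; point estimates are ensemble means and confidence
intervals are the [2.5, 97.5] percentile band. Vernaculars that never
co-occur with a resolved species fall back to a uniform draw over the
species of the map's most frequent family when a taxonomy is available
(else over all mapped species); fallback use is logged. Hierarchical
Bayesian priors over α are out of scope.

## Trait completion

Two gaps are treated separately:

- **Sampled species with missing cells** are completed by chained
  equations with predictive-mean matching: each missing trait is
  regressed on the other six over species with the trait observed, and
  the imputed value is drawn among the 5 donor values closest to the
  prediction. Donor pools are taxonomically restricted — congeners if
  at least 3 carry the trait, else confamilials (same minimum), else
  the whole table — which exploits the phylogenetic signal of traits.
  PMM guarantees imputed values lie within the donor pool's observed
  range; observed cells are never altered. Five sweeps suffice for the
  7-trait table. The ≥ 3-donor threshold is a package choice.
- **Species absent from the trait campaign** receive the complete
  7-vector of one donor drawn uniformly from sampled congeners (else
  confamilials, else all sampled species, logged). Copying vectors
  jointly preserves trait syndromes (e.g. the SLA–wood-density
  trade-off). The draw is repeated inside every propagation iteration
  so assignment uncertainty reaches the confidence bands; whether to
  redraw or fix the assignment was open, and redrawing is the
  conservative choice (wider, honest intervals).

Maximum height participates in imputation like the other six traits;
no separate rule is warranted. Functional distances are Euclidean on
z-scored traits: the traits mix units (µm, N, g/cm³, m²/kg, mm, m), and
unstandardized distances would be dominated by the largest-scale trait.
Whether to standardize was open; z-scoring is the defensible default
and the distance is invariant to affine rescaling of any raw trait.
Zero-variance traits are dropped from the distance with a warning.

## Diversity, composition, turnover

Hill numbers of order 0 and 2 measure richness and evenness; "taxonomic
evenness" is the order-2 Hill number itself (effective number of
dominant species), not divided by richness. Rao quadratic entropy is
the full double sum over the cohort's species pairs, using standardized
distances. CWM uses raw trait units so trajectories are interpretable
(mm of bark, m of height). Turnover is the relativized abundance
replacement (the replacement component of abundance difference, scaled
to [0, 1]) between each recruit cohort and the *whole* predisturbance
community of its plot, which removes the plots' strong taxonomic
signature; purely nested abundance change contributes zero.

## Null models

- The **taxonomic null** redraws, for each plot and time, the observed
  number of recruits from the relative abundances of "the community of
  the year and plot" — implemented as all living trees ≥ 10 cm at that
  census, the recruits' candidate pool (the contract does not define it
  more precisely). Sample size is conserved exactly.
- The **functional null** permutes whole trait rows across species
  labels, conserving the multiset of trait syndromes while severing
  their link to abundances. Row-wise permutation (not per-column
  shuffling) is deliberate: combinations of trait values move together.

Bands are percentile [2.5, 97.5] intervals of the per-iteration
observed − null difference; a time point is flagged significant when 0
falls outside. Null draws are *not* nested inside uncertainty
iterations: the pipeline runs a flat budget (100 iterations) in which
each iteration re-resolves the inventory, redraws the trait assignment,
and performs one taxonomic and one functional null draw, so all three
uncertainty sources enter one band at 100× cost rather than 100×100.
Nesting was open; the flat design keeps the default run tractable and
is logged in the manifest.

## Trajectory analysis

- **Smoothing** (presentation of CWM curves): cubic P-splines — a
  uniform, unclamped B-spline basis with a second-order difference
  penalty on coefficients, whose nullspace is exactly the linear
  functions — with the smoothing parameter minimizing the Gaussian REML
  score (residual variance profiled out). On degenerate (exactly
  linear) data REML is flat in the penalty, and the smoothest
  equivalent fit is preferred. Breakpoints are fitted on the raw,
  unsmoothed series.
- **Breakpoints**: the series is split into 1–3 segments, each fitted
  by OLS; for each break count the placement minimizing total SSE is
  found by exhaustive search over the 13-point grid with a minimum
  segment length of 3 observations, ties resolved toward the earliest
  break. Pure SSE cannot compare break counts (more breaks always fit
  at least as well), so the count is selected by BIC on the
  segment-wise Gaussian likelihood, with every candidate's score
  reported so other rules can be applied downstream. Breaks are
  reported as the first observation of the new segment and lie on the
  observation grid; no continuous-time estimation and no confidence
  intervals on break dates.
- **Gradient correlation**: per-plot summaries (maximum turnover;
  maximum absolute observed − null deviation for richness, evenness,
  Rao) against %AGB lost by Spearman rank correlation with mid-ranks;
  exact permutation p-values below 10 plots, the t approximation from
  10.

## Synthetic generator

The generator emulates a silvicultural-experiment design: twelve
6.25-ha plots, three undisturbed controls and nine plots spanning
12–56% AGB lost, censused annually from one year before disturbance to
year 30, with a 600-species pool. Defaults were chosen once, as
realistic for lowland neotropical forest, and are exposed in
`ScenarioConfig`:

- **Standing community**: 620 stems/ha ≥ 10 cm (3875 per plot), species
  drawn from a log-series abundance distribution (the classic tropical
  SAD; `sad_log_series_x = 0.99` gives a mean of ~21 stems per species
  draw). Species nest in ~170 genera and ~43 families, and guilds
  (15% pioneer, 25% light-demanding, 60% shade-tolerant species) are
  assigned at genus level with 10% within-genus deviation — the
  taxonomic trait signal that genus-restricted imputation exploits.
  Shade-intolerant guilds' stem shares are scaled down (×0.25 pioneer,
  ×0.6 light-demanding) so pioneers hold ~5% of standing stems: closed
  canopies keep shade-intolerant adults rare however speciose the
  guild.
- **Traits**: lognormal around guild-shifted medians (shade-tolerant
  baseline: 250 µm leaf thickness, 1.2 N toughness, 55 µg/cm²
  chlorophyll, 12 m²/kg SLA, 0.70 g/cm³ wood density, 4 mm bark, 35 m
  Hmax), with genus effects and a shared species-level acquisitiveness
  axis so SLA correlates negatively with wood density and toughness
  both between and within guilds.
- **Disturbance and recruitment**: disturbance kills a stem fraction
  equal to the fractional AGB loss; survivors then die at 1%/yr.
  Annual recruits are Poisson with mean 60 × (1 + 2 × %AGB/100) per
  plot — a doubling at 50% loss — and die at 2%/yr. Each recruit enters
  at 10–11 cm with a sub-threshold record in the previous census, so
  the crossing rule is exercised literally; individual growth is not
  simulated beyond a nominal increment.
- **The pioneer pulse**: with probability *w*(t) a recruit is drawn
  from the pioneer/light-demanding pool, where *w*(t) is a Gaussian
  kernel in time (peak 15 y, width 8 y) scaled by
  0.9 × min(%AGB/60, 1); any unimodal kernel satisfying the peak/width
  contract would do. Within the pulse, species are drawn by
  *recruitment potential* — an independent log-series fecundity draw,
  boosted ×3 for pioneers and sharpened by a power of 1.5 — not by
  standing abundance. This decoupling is essential and deliberate: the
  post-gap seed rain of a pioneer is unrelated to its near-absent adult
  population (the *Cecropia* pattern), and it is exactly the
  cohort-versus-community contrast that generates abundance
  replacement. Were the pulse drawn from standing abundances, cohort
  and community abundances would stay proportional species by species
  and turnover would never rise above its sampling baseline.
- **Degradation**: vernacular names group 2–3 species within a family
  for a configured fraction of names (default 0.5); generating α's are
  base abundances renormalized within the group. A configured fraction
  of trees (default 0.3) lose their botanical identity on every record.
  The trait campaign misses 40% of species entirely, and 13% of sampled
  species have 1–3 trait cells masked.

What the generator does *not* emulate: spatially explicit dispersal and
gap geometry, individual growth variation, basal-area/biomass dynamics,
sub-threshold demography, observer error in DBH, and temporal drift in
vernacular usage. Passing tests therefore validate the statistical
machinery — estimators, nulls, propagation, breakpoints — under a
plausible data-generating process, not the ecological conclusions one
would draw from any particular real forest.

## Problem sizes and determinism

The default experiment (12 plots × 3875 stems, ~79 000 trees, ~1.5 M
census records, 100 iterations) runs in about a minute on one CPU;
tests use 4-plot, 40-stems/ha scenarios for speed. One master seed
spawns independent child streams per stage (pool, inventory,
identification loss, trait masking, imputation, iteration loop), so any
stage can be rerun reproducibly and a rerun of the whole pipeline with
the same configuration is bit-identical. Numerical edge cases: empty
cohorts yield zero diversity and are flagged rather than erroring;
turnover clips floating noise at the [0, 1] boundaries; percentile
bands require at least 2 iterations; breakpoint SSE ties break toward
the earliest placement; a 1e-12 floor inside the BIC log keeps
noiseless series finite.

## Known limitations

- The association estimator pools co-occurrences over all censuses;
  if field naming conventions drift over decades, α's are averaged
  over regimes.
- The taxonomic null's candidate pool (standing community ≥ 10 cm)
  ignores the sub-threshold sapling bank from which recruits actually
  come.
- Breakpoint dates have no uncertainty quantification.
- The flat (non-nested) iteration design slightly conflates resolution
  and null-sampling variability within one band; the zero-ambiguity
  limit recovers the pure null band exactly.
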