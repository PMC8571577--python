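# recruits

Analysis of tree-recruitment trajectories after forest disturbance.

After a logging-type disturbance opens the canopy of a tropical forest,
the community reassembles through *recruitment* — trees crossing the
10 cm diameter-at-breast-height (DBH) census threshold. This package
quantifies how the taxonomic and functional composition of successive
recruit cohorts diverges from, and returns to, the predisturbance
community along a disturbance-intensity gradient (% aboveground biomass
lost, %AGB), while propagating the taxonomic uncertainty inherent to
field inventories in which trees carry vernacular names that map
ambiguously onto botanical species.

It is written for community ecologists working with longitudinal forest
inventories (annual censuses of mapped trees ≥ 10 cm DBH, a species ×
trait table with gaps, and a plot-level disturbance table), and ships a
fully ground-truthed synthetic inventory generator so every stage can be
validated without access to restricted station data.

## What it computes

For each plot and each observation time *T* (years since disturbance;
5, 7, …, 29 by default) the recruit cohort is the set of trees below
10 cm DBH two years before *T* and at or above it at *T*; disturbance
survivors are excluded. On each cohort's abundance vector
*p* = (*p*₁, …, *p*_S):

- **Taxonomic diversity** — Hill numbers of order 0 (richness *S*) and
  2 (inverse Simpson, 1/Σ *p*ₛ², "taxonomic evenness");
- **Functional diversity** — Rao quadratic entropy
  *H*(P) = Σₛ′ Σₛ″ *p*ₛ′ *p*ₛ″ *d*ₛ′ₛ″, with *d* the Euclidean distance
  between species in standardized 7-trait space (leaf thickness,
  toughness, chlorophyll, SLA, wood specific gravity, bark thickness,
  maximum height);
- **Functional composition** — community-weighted mean (CWM) traits
  Σₛ *p*ₛ · traitₛ, smoothed with REML-selected penalized splines;
- **Turnover** — relativized abundance replacement against the whole
  predisturbance community:
  *T*_ab = (Σᵢ|*x*ᵢᵃ − *x*ᵢᵇ| − |Σᵢ*x*ᵢᵃ − Σᵢ*x*ᵢᵇ|) / Σᵢ max(*x*ᵢᵃ, *x*ᵢᵇ).

Observed trajectories are compared to two null models (100 iterations,
percentile 95% bands on the observed − null difference): a **taxonomic
null** resampling the observed number of recruits from the standing
community of the plot and year, and a **functional null** permuting
whole trait vectors across species. Vernacular→species ambiguity is
propagated by multinomial resolution (one draw per tree per iteration)
from association probabilities estimated by pooled co-occurrence
counting. Missing trait cells are imputed by chained equations with
genus/family-restricted donors; species absent from the trait campaign
receive a congener's (or confamilial's) full trait vector, redrawn per
iteration. Trajectory shifts are located by Bai–Perron-style
piecewise-linear breakpoint search (exhaustive SSE minimization, BIC
model-count selection), and trajectory summaries are correlated with
the %AGB gradient by Spearman tests (exact permutation p-values below
10 plots).

## Worked example

```python
from recruits import RunConfig, ScenarioConfig, run_pipeline

# a scaled-down four-plot gradient: two controls, 30% and 60% AGB lost
scenario = ScenarioConfig(
    n_plots=4, agb_lost_pct=(0, 0, 30, 60),
    n_species=60, stems_per_ha=40, base_recruits_per_year=8,
)
result = run_pipeline(RunConfig(scenario=scenario, n_iter=50, seed=42))

print(result.correlations.to_string(index=False))
print(result.turnover.groupby("plot_id")["value"].max().round(3).to_string())
```

prints

```
  metric           summary       rho  p_value
turnover         max_value  0.948683 0.166667
richness max_abs_null_diff  0.316228 0.666667
evenness max_abs_null_diff  0.316228 0.666667
     rao max_abs_null_diff -0.210819 0.833333
plot_id
P01    0.025
P02    0.024
P03    0.069
P04    0.169
```

Maximum turnover rises monotonely along the tiny gradient (ρ = 0.95;
with only 4 plots the exact permutation p-value cannot fall below 1/12,
hence 0.17), and the most disturbed plot replaces ~17% of its
predisturbance abundance at the trajectory peak while the controls stay
near 2%. The richness/evenness summaries are too noisy to order four
small plots — at the full 12-plot design they become strongly positive.
`run_pipeline(..., out_dir=...)` additionally writes eight CSVs
(trajectories with 95% CIs, null bands, CWM curves, breakpoints,
correlations, cohort sizes, association map) plus a JSON manifest.

The same stages are scriptable from a shell:

```sh
recruits simulate --seed 42 --out sim/          # synthetic inventory bundle
recruits extract --inventory sim/inventory.csv --disturbance sim/disturbance.csv \
        --disturbance-year 1987 --out cohorts.csv
recruits run --seed 42 --out results/           # full pipeline
```

## Layout

- `src/recruits/inventory_io.py` — inventory/disturbance tables, recruit
  cohorts, predisturbance communities
- `src/recruits/synthetic_forest.py` — ground-truthed scenario generator
- `src/recruits/taxonomy_resolution.py` — association probabilities,
  multinomial resolution, uncertainty propagation
- `src/recruits/trait_processing.py` — trait imputation, assignment,
  standardized functional distances
- `src/recruits/metrics.py` — Hill numbers, Rao entropy, CWM, turnover
- `src/recruits/null_models.py` — taxonomic/functional nulls and bands
- `src/recruits/trajectory_analysis.py` — P-spline smoothing,
  breakpoints, Spearman gradient tests
- `src/recruits/pipeline.py`, `cli.py` — orchestration and the
  `recruits` command

See `docs/methods.md` for the modelling choices and their rationale.
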