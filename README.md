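# lepisync

Spatial population synchrony in multi-site, multi-species monitoring data.

Long-term butterfly transect programmes record, for tens of species at
once, which visits each species was seen on. Populations of some species
rise and fall in parallel across sites while others fluctuate
independently, and two classic mechanisms compete to explain the
difference: dispersal linking sites, and spatially correlated climate
forcing (the Moran effect). `lepisync` implements the complete analysis
for comparing these drivers across an assemblage:

1. **Synchrony index.** For each species, the fraction of days positive
   FDP<sub>ij</sub> (detections / visits at site *j* in year *i*) is
   differenced year-over-year, and synchrony is the unweighted mean of
   pairwise Pearson correlations of ΔFDP between sites, after inclusion
   rules (a site is dropped for a species absent there ≥ 8 years; a
   species needs ≥ 3 sites).
2. **Climate sensitivity.** Per species, a hierarchical Bayesian binomial
   regression with logit(p<sub>ij</sub>) = μ<sub>j</sub> +
   β<sub>1j</sub> winter temp + β<sub>2j</sub> spring temp +
   β<sub>3j</sub> winter precip + β<sub>4j</sub> spring precip +
   β<sub>5j</sub> summer precip + β<sub>6j</sub> SSTA +
   β<sub>7j</sub> year, site coefficients drawn from transect-wide
   normals (μ<sub>j</sub> ~ N(μ<sub>μ</sub>, τ<sub>μ</sub>), β<sub>kj</sub> ~
   N(μ<sub>βk</sub>, τ<sub>βk</sub>), precisions with vague Gamma
   hyperpriors), sampled by Gibbs-within-Metropolis MCMC. Posterior means
   of the transect-wide slopes are the species' climate responses.
   Predictors are z-scored water-year seasonal aggregates; SSTA is the
   December–February mean sea-surface-temperature anomaly (Niño 3.4), the
   ENSO index.
3. **Factor analyses.** Maximum-likelihood factor analysis reduces four
   dispersal-related traits (wingspan, geographic range, diet breadth,
   elevational range) and the five local-weather responses to two latent
   factors each; the ENSO response stays standalone.
4. **Structural equation models.** Three canned SEMs (dispersal-only,
   climate-only, combined; model df 4, 9 and 18) compare how much
   interspecific variance in synchrony each driver explains (R² of the
   synchrony equation), with abundance, average sites occupied and
   population trend as covariates, plus migrant-exclusion and
   random-removal (drop 9 of 65, refit) experiments.

A seeded synthetic-data generator produces complete studies (observations,
weather, SSTA series, traits) with known ground truth at the monitored
design's scale — 10 sites across 2750 m of elevation, 65 species, 27 years
of biweekly visits — so the entire pipeline is testable end to end.

## Worked example

```python
from lepisync import synchrony, climate, hier_bayes
from lepisync.synthetic import SimulationConfig, generate_study

study = generate_study(SimulationConfig(seed=42))

fdp = synchrony.compute_fdp(study.observations)
kept, excluded = synchrony.apply_inclusion_rules(fdp)
result = synchrony.synchrony_index(synchrony.compute_delta(kept))
print(result.table.head(3).round(3).to_string(index=False))
```

```
species_id  index  n_sites  n_pairs  mean_overlap_years
     sp001  0.174       10       45                26.0
     sp002  0.739        3        3                26.0
     sp003  0.126       10       45                26.0
```

Each row is one species: `index` is its mean pairwise ΔFDP correlation
(sp002 is highly synchronized, sp001 and sp003 only weakly so), computed
from `n_pairs` site pairs sharing ~26 ΔFDP years. Across the 64 species
surviving the inclusion rules the mean index is 0.157.

```python
seasonal = climate.aggregate_seasonal(study.weather)
enso = climate.enso_winter_mean(study.ssta)
design = hier_bayes.build_design("sp001", fdp, seasonal, enso)
draws = hier_bayes.run_mcmc(design, n_iter=5000, burn_in=1000,
                            chains=2, seed=42)
print(hier_bayes.summarize(draws).response.round(3).to_string())
```

```
winter_temp     -0.224
spring_temp      0.060
winter_precip    0.252
spring_precip    0.135
summer_precip    0.042
ssta             0.158
year            -0.053
```

These are sp001's transect-wide climate responses (posterior-mean slopes
on z-scored predictors): detection odds rise ~29% per sd of winter
precipitation, with a positive ENSO response. The generating truth for
this species was (−0.04, 0.08, 0.12, 0.04, 0.09, 0.15, −0.09) — within
posterior uncertainty for a 10-site, 27-year series.

The full pipeline (per-species fits, factor analyses, the three SEMs and
both removal experiments) runs from one config:

```python
from lepisync.pipeline import PipelineConfig, run_pipeline
report = run_pipeline(PipelineConfig(simulation=SimulationConfig(),
                                     seed=42, out_dir="out"))
```

or from the shell: `lepisync run --config config.yaml`, with stagewise
subcommands `simulate`, `synchrony`, `climate-prep`, `fit-bayes`,
`factors` and `sem`.

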