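# msocc — multispecies occupancy modeling with imperfect detection

No survey detects every species that is present. For rare or
difficult-to-catch species this *imperfect detection* turns true
presences into recorded absences, biasing site-level species richness
and every downstream community analysis built on the presence–absence
matrix. `msocc` implements, as a tested pipeline, a workflow for
quantifying that bias in replicated community surveys (the motivating
case is a stream-fish assemblage trapped at ~31 creek sites, three
replicates in each of two survey years):

1. **Site and species filtering** — enforce spatial independence by
   removing any site whose home-range reach (from an allometric
   home-range area for the largest fish caught) overlaps a downstream
   neighbor's, and enforce closure by removing species not detected in
   both survey years.
2. **Hierarchical multispecies occupancy model** — for species *i* at
   site *j* with replicate *k*:

   ```
   logit(ψ[i,j])   = u[i] + a1[i]·width1[j] + a2[i]·distance1[j]
   logit(p[j,k,i]) = v.YR1[i]·(1 − Year[k]) + v.YR2[i]·Year[k]
   z[i,j]  ~ Bernoulli(ψ[i,j])
   y[i,j,k] ~ Bernoulli(z[i,j] · p[j,k,i])
   ```

   with every species-level parameter drawn from a community-level
   normal distribution (weakly informative hyperpriors). Inference is a
   data-augmented Metropolis-within-Gibbs sampler with Gelman–Rubin
   R-hat convergence checks.
3. **Informed datasets** — non-detections whose posterior occupancy
   probability meets a threshold (defaults 95%, 75%, 50%) are recoded
   as presences; per-site richness is compared before and after.
4. **Ordination comparison** — correspondence analysis of each matrix,
   axis signs resolved, then resistant-fit (repeated-median) Procrustes
   superimposition; the per-landmark residuals show which sites and
   which species change most once detection is accounted for.

A synthetic-data generator with known ground truth (the exact
data-generating process above) makes every stage testable end to end.

## Worked example

```python
import msocc

# simulate a 12-species, 31-site, 6-replicate community survey
ds = msocc.generate_dataset(n_species=12, n_sites=31, seed=1)

config = msocc.ModelConfig(n_chains=3, n_iter=30_000, burn_in=5_000,
                           thin=25, seed=1)
samples = msocc.sample_posterior(ds.detections, config)
print("max R-hat:", msocc.convergence_report(samples)["rhat"].max().round(3))

P = msocc.occupancy_probability_matrix(samples, "conditional")
observed = msocc.pool_detections(ds.detections)
informed = {t: msocc.apply_threshold(observed, P, t) for t in (0.95, 0.75, 0.5)}
report = msocc.richness_comparison(observed, informed)
print(report.summary[["threshold", "max_gain", "sites_gaining_ge1"]])
```

prints

```
max R-hat: 1.009
   threshold  max_gain  sites_gaining_ge1
0       0.95         0                  0
1       0.75         0                  0
2       0.50         2                 24
```

i.e. at the permissive 50% occupancy threshold the model judges 24 of
the 31 sites to be missing at least one species (up to two) from the
raw detection matrix, while at the stricter thresholds no
non-detection in this particular simulated community is confident
enough to recode. Comparing the correspondence analyses of the
observed and 50%-informed matrices:

```python
ca_obs = msocc.correspondence_analysis(observed)
ca_inf = msocc.correspondence_analysis(informed[0.5])
aligned = msocc.align_configurations(ca_obs.col_scores, ca_inf.col_scores)
fit = msocc.resistant_fit_procrustes(ca_obs.col_scores, aligned)
print(fit.residuals.sort_values(ascending=False).head(3).round(3))
```

```
species_code
SP05    1.983
SP03    1.355
SP06    0.768
Name: residual, dtype: float64
```

the species Procrustes residuals single out which taxa's ordination
positions are most sensitive to imperfect detection.

The same workflow is scriptable from a shell (`msocc simulate`,
`msocc filter`, `msocc fit`, `msocc inform`, `msocc ordinate`, or
`msocc run-all --config pipeline.yaml`), with all artifacts written as
headered CSV/JSON plus a checksummed run manifest.

## Layout

| module | contents |
| --- | --- |
| `msocc.synthetic_data` | community hyperparameters, ground-truth simulation |
| `msocc.site_filter` | home-range reach, spatial-independence and closure filters |
| `msocc.occupancy_model` | likelihood, Gibbs sampler, R-hat, posterior occupancy |
| `msocc.informed_dataset` | threshold recoding, richness comparison |
| `msocc.ordination` | correspondence analysis, resistant-fit Procrustes |
| `msocc.pipeline` / `msocc.cli` | config-driven orchestration, `msocc` CLI |

See `docs/methods.md` for the statistical details and design choices.
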