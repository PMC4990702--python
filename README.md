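# beepersist

Dynamic multi-species Bayesian occupancy modelling of wild-bee
population persistence under exposure to neonicotinoid-treated oilseed
rape.

## The problem

Volunteer recording schemes hold decades of opportunistic occurrence
records for hundreds of wild bee species — presence-only lists from
uneven, unstructured effort. This package implements, as a tested
reusable pipeline, an analysis linking year-to-year *persistence* of
species in 5 km grid cells to three annual covariates: the cover of
oilseed rape, the exposure to neonicotinoid seed treatments (cover ×
regional proportion of the crop treated), and a Foliar Insecticide
Impact (FII) index summarising sprayed insecticides. It is aimed at
ecologists and biostatisticians working with recording-scheme data who
need occupancy trends that are honest about imperfect detection, and a
counterfactual answer to "what would occupancy look like had
neonicotinoids never been used?".

## The model

Latent occupancy z of species *i* in cell *j* follows a two-state
Markov chain,

    z[i,j,t] ~ Bernoulli( z[i,j,t−1]·φ[i,j,t] + (1 − z[i,j,t−1])·γ[i] ),
    logit φ[i,j,t] = β0[i] + β1[i]·OSR[j,t−1] + β2[i]·NEON[j,t−1] + β3[i]·FII[j,t−1],

and a survey (unique date × 1 km cell) detects an occupying species with

    logit p[i,k] = β4[i] + β5[i]·short[k] + β6[i]·long[k] + α[t],

where short/long indicate 2–3-species and >3-species lists (an effort
proxy) and α[t] is a year effect. Species effects are random; the
persistence coefficients β1–β3 are drawn from separate distributions for
oilseed-rape foragers and non-foragers, and the contrast between those
group means — computed pairwise across posterior draws — is the headline
quantity. The latent chain is marginalised exactly by the forward
algorithm and the posterior is sampled by an adaptive
Metropolis-within-Gibbs sampler (numba-compiled); a data-augmented
sampler with explicit states provides an independent cross-check. See
`docs/methods.md` for priors, numerical choices and limitations.

A synthetic-data generator emulates every input — landscape, biennial
crop and pesticide surveys, volunteer visit lists with realistic effort
structure, and occupancy dynamics generated from the model itself — so
the whole pipeline runs and validates without any external data.

## Worked example

```python
from beepersist import OccupancyModel, simulate_study

study = simulate_study(seed=1)          # full synthetic study, known truth
model = OccupancyModel(study.dataset, study.truth.panel)
res = model.fit(chains=3, iterations=2000, burnin=1000, thin=2, seed=1)

e = res.group_effect("neonic", "forager")
print(f"forager exposure effect: {e.posterior_mean:.2f} "
      f"({e.ci95_low:.2f}, {e.ci95_high:.2f}), "
      f"P(<0) = {e.fraction_below_zero:.3f}")
d = res.group_difference("neonic")
print(f"difference (non-forager − forager): {d['mean']:.2f} "
      f"({d['ci95_low']:.2f}, {d['ci95_high']:.2f})")
```

prints (the simulation's generating hyper-means are −1.37 for foragers
and −0.46 for non-foragers):

```
forager exposure effect: -1.32 (-1.71, -0.90), P(<0) = 1.000
difference (non-forager − forager): 1.02 (0.58, 1.41)
```

i.e. the fitted model recovers the strongly negative exposure effect for
crop-foraging species, and the group difference — positive when
foragers are the harder-hit group — matches the realised difference of
the simulated species sample (0.99 for this seed). Counterfactual
trajectories and the percent of extant cells each species loses to the
exposure come from the same results object:

```python
traj = res.project_occupancy("no_neonic")   # idealised: no use from 2002
loss = res.occupancy_loss()                 # % loss per species, final year
print(loss.head(3)[["species", "pct_loss"]])
```

```
  species   pct_loss
0  sp_f02  44.108497
1  sp_f12  42.079896
2  sp_f07  39.550167
```

The species losing the most occupied cells to the exposure are, as the
generating model implies, crop foragers (the `sp_f*` ids).

The command-line interface mirrors the pipeline:
`bee-persist simulate | fii | assemble | fit | summarize`.

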