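# Methods

## The model

`beepersist` fits a multi-species dynamic occupancy-detection model to
opportunistic (volunteer-collected) occurrence records. The latent state
z_{i,j,t} ∈ {0,1} is the presence of species *i* in 5 km grid cell *j*
in year *t*:

    z_{i,j,1}  ~ Bernoulli(ψ0_i)
    z_{i,j,t}  ~ Bernoulli( z_{i,j,t−1}·φ_{i,j,t} + (1 − z_{i,j,t−1})·γ_i )

Occupied cells persist with probability φ; empty cells are colonised
with species-specific probability γ_i. Persistence is a logit-linear
function of last year's centred covariates:

    logit φ_{i,j,t} = β0_i + β1_i·OSR_{j,t−1} + β2_i·NEON_{j,t−1} + β3_i·FII_{j,t−1}

where OSR is oilseed-rape cover, NEON the neonicotinoid seed-treatment
exposure (cover × regional proportion of the crop treated) and FII the
foliar-insecticide impact index. Because the covariates are centred,
inverse-logit(β0_i) is the persistence in the average occupied cell, and
β2_i is the change in the log odds of persistence per unit exposure —
the quantity of central scientific interest (the hypothesis is β2 < 0,
more strongly for species that forage on the crop).

Detection is conditional on presence. A *survey* is a unique date ×
1 km-cell combination; its species-list length proxies effort through
two binary covariates (short list = 2–3 species, long list = >3):

    logit p_{i,k} = β4_i + β5_i·short_k + β6_i·long_k + α_{t(k)}

with α_t a year random effect, so inverse-logit(β4_i) is the probability
that a single-species survey in an average year records species *i*.
Treating the three list categories as separate data streams (rather than
a monotone list-length effect) reflects that many records are casual
single-species observations rather than attempts at complete lists.

Species effects are random. γ, β0, β4–β6 come from one common normal
distribution each (mean and SD estimated); the persistence covariate
coefficients β1–β3 come from *separate* normal distributions for
oilseed-rape foragers and non-foragers, so the group hyper-means
μ(β2, forager) and μ(β2, non-forager) — and their paired-draw difference
— are the headline estimands.

### Priors

"Uninformative" priors are operationalised as: Normal(0, 10) on all
hyper-means, half-Normal(2.5) on hyper-SDs and on the year-effect scale
(half-Cauchy(2.5) available via `FitConfig.sd_prior`), and Uniform(0,1)
on the initial occupancy probabilities ψ0_i. These are the package's
choices; on logit scales an SD of 10 is effectively flat, and results at
the fitted data sizes are insensitive to doubling any of these scales.

## Likelihood and samplers

The default sampler integrates the latent chain out analytically: for
each species × site the marginal likelihood of the detection history is
computed by the forward algorithm over the two-state Markov chain, with
unsurveyed years contributing only transition factors. Detection
probability depends on a visit only through its list category and year,
so the data reduce without loss to per (site, year, category) visit and
detection counts. The forward pass is exact; the test suite checks it to
1e-10 against brute-force enumeration of all 2^T occupancy paths.

Sampling is adaptive random-walk Metropolis within Gibbs: scalar updates
for every species-level parameter and year effect (step sizes tuned to a
0.44 acceptance rate during burn-in only, then frozen), conjugate Gibbs
draws for the hierarchical means, and Metropolis on the log of each
hierarchical SD. Kernels are numba-compiled; per-species emission and
persistence caches make a full update sweep O(S·J·T) with a small
constant.

A second, data-augmented sampler keeps z explicit — forward-filtering
backward-sampling for the states, conditional Metropolis/Gibbs for
parameters — mirroring the formulation a BUGS-style implementation uses.
It is slower and exists as an independent route to the same posterior;
the suite checks the two samplers agree on small datasets. The two
routes never share likelihood code paths.

The reference protocol is 3 chains × 10,000 iterations, burn-in 5,000,
thinning 3. The scaled-down validation protocol used by the acceptance
runs is 3 × 2,000 with burn-in 1,000 and thinning 2, which finishes in a
few minutes at the default synthetic scale while leaving Monte-Carlo
error well below the hyper-parameter posterior SDs. Convergence is
monitored with the Gelman–Rubin statistic on all hyper-parameters plus
five randomly chosen species-level parameters; R̂ ≤ 1.1 is the reporting
threshold and non-convergence flags metadata rather than aborting. The
R̂ implementation uses the classic between/within ratio floored at 1.0
(finite-sample noise can push the raw ratio fractionally below one); a
split-chain variant is available via `rhat(..., split=True)`.

## Covariates

* **FII.** For each foliar-applied active ingredient,
  FII contribution = 3 · Z · (DT50/4) · (M/A), where Z ∈ {5,3,1} by the
  acute contact LD50 brackets (<1, 1–100, >100 µg/bee; boundary values
  fall in the middle class, configurable), DT50/4 estimates the plant
  surface half-life in days, and M/A is kg of active ingredient per
  hectare sprayed in the region-year. Contributions sum over
  ingredients; regional scores map to 5 km cells by majority region
  (supplied as a lookup table — no polygon geometry is performed). The
  leading factor 3 is the bee-exposure weighting of the EIQ scheme the
  index derives from; it is a redundant common factor retained for
  comparability. Only the bee component of the EIQ is computed.
* **Interpolation.** Crop-cover and pesticide surveys run on alternate
  years; interior gaps are filled with the mean of the flanking surveys
  before any product is formed (both the cover and the treated
  proportion are interpolated, then multiplied). Gaps wider than two
  years are an error, not silently bridged.
* **Exposure.** NEON_{j,t} = cover_{j,t} × proportion-treated_{region(j),t};
  proportions before the first treatment year default to zero unless the
  input table supplies trial-era values.
* **Centring.** Covariates are centred (not scaled) on their grand mean
  over all modelled cell-years; the means are stored because the
  counterfactual zeroes exposure on the *raw* scale and then re-centres
  with the original means, so the fitted coefficients keep their
  meaning. Cover and exposure enter the model in thousands of hectares
  per 5 km cell, the scale on which coefficients of order one are
  interpretable; input CSVs carry plain hectares and
  `build_covariate_panel(osr_scale=1e-3)` performs the conversion.
* **Lagging** happens inside the model (persistence into year t uses
  covariates at t−1); the panel stores unlagged values so there is one
  source of truth.

## Survey assembly rules

Records → visits (unique date × 1 km cell; coarser-resolution records
are excluded with a logged count) → drop 1 km cells surveyed in fewer
than two distinct years → collapse configured species aggregates
(recomputing list lengths) → retain species recorded on ≥ `min_surveys`
visits. Detections of non-retained species still count toward list
length: the list measures recording effort, not the modelled community.
The species threshold is applied after the cell filter, matching the
narrative order of the data-cleaning protocol. Occupancy is modelled at
the 5 km scale, so visits pool under the parent cell; site-years with no
visits remain in the model with their states marginalised.

## Counterfactual projection and loss

Trajectories are *fitted values*: for each posterior draw, expected
occupancy is propagated from that draw's ψ0 through the dynamics
(ψ_t = ψ_{t−1}φ + (1−ψ_{t−1})γ per site), not re-conditioned on the
detections year by year. The no-neonicotinoid scenario zeroes raw
exposure from the first treatment year (2002) onward; years before it
are identical by construction, and when all β2 draws are ≤ 0 the
counterfactual dominates the factual trajectory within every draw —
both properties are tested exactly.

Percent loss of extant cells for a species is
100 × (counterfactual − factual) / counterfactual expected occupied-cell
proportion in the final modelled year. By default the ratio is formed
within each posterior draw and averaged (`method="draws"`); forming it
from posterior-mean trajectories (`method="mean"`) is available since
the operationalisation is not uniquely determined. A zero counterfactual
denominator reports as missing. Species lists at the 10/15/20 % loss
thresholds accompany the table.

The group-difference posterior is computed pairwise within draws and
reported as non-forager minus forager, the convention under which a more
negative forager effect yields a positive difference.

## Synthetic data: what it emulates, and what it does not

The generator produces all five input tables plus ground truth. It
emulates: nested 1 km/5 km grids partitioned into regions; biennial
survey tables (exercising interpolation); a treated-proportion ramp
rising on the logit scale from 37.4 % (2002) to 83.0 % (2011) with
small regional jitter and zero before 2002 (optional trial-era cells);
spatially heterogeneous, temporally drifting crop cover; a pesticide
usage/properties pair spanning all three toxicity classes, with
persistent between-region differences in application rates and only
mild annual drift — so the foliar index varies mainly in space, as a
regionally-surveyed quantity does, and is not confounded with the
temporal adoption ramp of the seed treatments; volunteer
effort with per-cell visit rates, inactive cell-years, and a latent
effort class per visit (single/short/long) calibrated so that about half
of realised surveys are single-species lists; and occupancy/detection
generated from exactly the fitted model's equations. Default truth
hyper-means for the persistence effects are the reference group-level
effect sizes (exposure −1.37/−0.46, cover 1.06/−0.09, foliar index
−0.017/−0.013 for foragers/non-foragers), with hyper-SDs of 0.25 (0.01
for the foliar index, whose covariate is on a much larger numeric
scale), so recovery experiments target those printed values. The default
scale is 20 forager + 15 non-forager species, 150 sites × 5 cells,
1994–2011.

One deliberate approximation: the effort class that sets a visit's
detection probabilities is latent, while the covariate the model sees is
the category of the *realised* list (background species pad lists up to
the class target, but modelled detections can overflow the band, in
roughly 5–10 % of visits under defaults). This keeps the
records→dataset round trip exact and mirrors the endogeneity of
list-length covariates in real recording-scheme data. Its visible
consequence is a modest bias in the detection submodel (β4 low, β5/β6
high relative to truth); the persistence hyper-parameters — the
quantities the analysis is about — recover within Monte-Carlo error in
the test suite. The generator does not emulate bee phenology within the
season, spatial autocorrelation or recorder home ranges, misidentified
records, or abundance; passing recovery tests therefore demonstrates
correctness of the machinery under the model's own assumptions, not
robustness to the violations real data contain.

## Numerical choices and degenerate inputs

* Logits are clipped at ±35 before the logistic, keeping log(p) and
  log(1−p) finite; an impossible history returns −∞ (−1e300 inside the
  compiled kernels).
* The forward pass renormalises its scaled state only when the running
  product underflows 1e-280, so the inner loop is multiply-bound.
* Chain seeds fan out deterministically from the master seed via
  `numpy.random.SeedSequence`; identical seeds reproduce draws
  bit-for-bit.
* Species never detected anywhere still contribute through the marginal
  likelihood; a site with one modelled year uses only ψ0 and detection.
* LD50/DT50 must be strictly positive; boundary LD50 values (exactly 1
  or 100) take the middle toxicity class by default.
* Equal-tailed 95 % intervals (2.5/97.5 percentiles) throughout, not
  HPD.

## Known limitations

* **Detection-trend / occupancy-trend aliasing.** The detection year
  effects α_t are only softly identified from the cross-category
  structure of the lists; their amplitude is shrunk toward the
  N(0, σ_α) prior, and any chance *trend* in the realised α series that
  the fit does not recover is absorbed by the persistence covariates
  with a matching temporal profile — chiefly the exposure ramp. At the
  default synthetic scale this contributes a seed-level spread of
  roughly ±0.2 to the recovered exposure hyper-means (with converged,
  well-mixed chains), which is why recovery checks are judged against
  Monte-Carlo/seed spread rather than a fixed small tolerance. Real
  analyses of this design face the same aliasing; more surveys per
  year, and covariates whose time profile differs from any smooth
  detectability drift, are what tighten it.

* The year effect α_t is shared across species, as the detection
  formulation specifies; species-specific year effects are out of scope.
* No spatial autocorrelation between cells and no phylogenetic
  covariance between species.
* The scalar-Metropolis sampler mixes slowly for some hierarchical SDs
  at short chain lengths (R̂ up to ~1.5 on those scales under the
  reduced protocol); hyper-means, the reported estimands, converge much
  faster. The long reference protocol resolves this.
* The counterfactual is a projection under the fitted correlational
  model, not a causal estimate.
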