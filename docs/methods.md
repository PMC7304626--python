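# Methods

## The model chain

Biomass of line *j* in environment *e* is predicted as

    BM(j, e) = τ · BM_TSG(j, e)

where BM_TSG is the simulated aboveground biomass at the termination of
seed growth and τ is a single scaling coefficient estimated on training
lines as the mean ratio of observed to simulated biomass.  BM_TSG sums
daily increments from the growth start date to TSG:

    ΔBM_i = IRUE · TRF_RUE(T_i) · FINT(LAI_i) · PAR_i

- **IRUE = 2.2 g MJ⁻¹** (maximum radiation-use efficiency) and the
  extinction coefficient **k = 0.6** are treated as constants across lines
  and environments.
- **TRF_RUE(T)**: 0 below 10 °C, linear to 1 at 25 °C, flat to 32 °C,
  linear back to 0 at 42 °C.  The descending branch is implemented as
  (42 − T)/10; a sign-flipped version of this branch would be negative on
  (32, 42) and break TRF ∈ [0, 1], so the standard form is used.
- **FINT(LAI) = 1 − exp(−k·LAI)** (Beer's law).  The alternative form
  exp(1 − k·LAI) exceeds 1 for a bare canopy and decreases with leaf
  area, which contradicts the definition of an intercepted fraction, so
  Beer's law is used deliberately.
- **LAI** is reconstructed from leaf age and tiller count:
  LAI = β_leaf · Till · Σ_{l=1}^{LeafAge} (l·ΔLL)² / S, with
  β_leaf = 0.003 (leaf-shape coefficient), S = 0.0225 m² (225 cm² ground
  area per plant; ΔLL is kept in metres so LAI is dimensionless).  Leaf
  age is continuous; the emerging leaf contributes its squared length
  pro-rated by the fractional part.
- **TSG** is the first day on which post-heading degree days (simple sum
  of daily means) reach 630 °C·d.  Weather after TSG is irrelevant by
  construction.

Leaf age and tiller count follow piecewise-linear heat-unit models:
Leaf_i = min(ΔLeaf·HU_i, Leaf_MAX) and Till_i = 1 for HU_i ≤ 800 °C·d,
afterwards min(ΔTill·HU_i, Till_MAX).  The jump at 800 °C·d is part of
the model and is not smoothed.  Heat units default to the simple daily
mean sum; a base-8 variant (Σ max(0, T − 8)) is available via
`heat_unit_mode="base8"`.  ΔLL = (len₁₁ − len₅)/6 from the final blade
lengths of the 5th and 11th leaves.

## Phenology

Developmental stage DVS accumulates daily rates
f(T)^α·g(P)^β/G inside the photoperiod-sensitive window
0.145+0.005G ≤ DVS ≤ 0.345+0.005G and f(T)^α/G outside it; heading is the
first day with DVS ≥ 1.  f is a beta-type response with cardinal
temperatures 8/30/42 °C; g equals 1 below the 10 h optimum and falls to 0
at 24 h.  Day length comes from the standard solar-declination formula
with a configurable sun-elevation threshold (default −0.833°,
sunrise/sunset; civil-twilight variants differ by ~30–50 min and can be
set in the config).  Window membership is decided on the start-of-day
DVS.  Emergence defaults to the sowing date (configurable offset), since
sowing is what multi-environment trials record.

### Fitting (α, β_P, G) by PSO

Per line, a global-best particle swarm (50 particles, 200 iterations,
inertia 0.7, c1 = c2 = 1.5) minimizes the RMSE in days between simulated
and observed heading over the box α ∈ [0, 10], β_P ∈ [0, 15],
G ∈ [40, 200] — bounds that bracket plausible rice values.  Two
numerical choices matter:

- The objective is the RMSE of **integer** simulated heading days plus a
  0.05-weighted term using the fractional DVS = 1 crossing time.  The
  integer landscape is piecewise constant; the fractional term restores a
  gradient inside each plateau without moving the optimum.
- Each iteration the worst tenth of the swarm (never the global best) is
  resampled uniformly in the box ("random immigrants").  The landscape is
  multimodal — without this, a minority of lines stall in local optima.

Particles that never reach heading in a trial are penalized with a
pseudo-observation of series length + 50 days.  If no initial particle
heads anywhere, the swarm is re-initialized (up to 3 retries) before
failing.  The heading computation inside the optimizer uses an
O(log days) phase decomposition (cumulative sums + binary search over the
pre-window / in-window / post-window phases); the day-by-day loop is kept
as an independent reference and the two are property-tested against each
other.

### The gene → parameter map (ELM)

An extreme learning machine maps the coded genotypes of the six
heading-date genes (each represented by its nearest SNP) to (α, β_P, G):
inputs standardized, one random sigmoid hidden layer (50 nodes, seeded —
refitting with the same seed reproduces the weights exactly), output
weights by ridge least squares (penalty 1e-3, intercept unpenalized).
Predictions are clamped to the PSO bounds box.  The hidden size and
penalty were chosen for stability at the ~112-line panel scale.

## Genomic prediction

Markers are coded +1/−1 for the parental homozygotes and 0 for
heterozygotes — the natural additive coding for a nearly homozygous RIL
population.  Missing genotype cells are imputed to the per-marker mean
(the handling of missing data is this package's choice).  Four methods:

- **RR / LASSO**: scikit-learn Ridge/Lasso; penalty by seeded internal
  5-fold CV minimizing MSE (plain minimum, no one-standard-error rule),
  LASSO over a 40-point path.  LASSO is the default first-step method.
- **GBLUP**: y = 1μ + g + e with g ~ N(0, σ²_g A); A is VanRaden-style
  X_c X_cᵀ scaled by trace/n so the mean diagonal is exactly 1, which
  puts σ²_g on the phenotypic-variance scale.  Variance components by
  spectral REML (one eigendecomposition, profile likelihood over
  σ²_g/σ²_e on a log grid, bounded scalar optimization).  On any full-rank
  toy, GBLUP fitted values coincide with marker-space ridge at penalty
  (σ²_e/σ²_g)·normalizer to ~1e-14 (tested).
- **RKHS**: Gaussian-kernel ridge; bandwidth by the median heuristic on
  squared marker distances, penalty by internal CV.

Narrow-sense heritability is σ²_g/(σ²_g + σ²_e) from the GBLUP fit,
clamped to [0, 1].

## Validation scheme

Replicated 10-fold cross-validation **among genotypes**.  Tested scheme:
training phenotypes and validation weather from the same year.  Untested
scheme: step-1 models and τ are trained entirely on the training year;
only the weather switches to the target year, and scoring uses the target
year's observations.  Per replicate, out-of-fold predictions are pooled
before computing Pearson r, RMSE, and the slope of observed regressed on
predicted (pooling stabilizes the slope at ~12 lines per fold; per-fold
averaging is not used).  τ is recomputed inside every fold from training
lines only; the heading-date step depends only on markers and weather and
is therefore computed once per run.  No phenotype of a held-out line can
reach its own prediction by construction (and a corruption test asserts
it).  Lines whose DVS simulation never reaches heading are flagged and
excluded from metrics with their count reported.

IntML trains its second step on the GP-predicted (not observed)
intermediates of the training lines, keeping the featurization of
training and test lines identical.  IntML2 uses a random forest with
max_features = 2 (mtry = 2) and 500 trees, other hyperparameters at
library defaults.  Panicle weight, when requested, is biomass × a
GP-predicted harvest index.

## The synthetic-data generator

The generator emulates the study system and shares the growth/phenology
/CGM code paths with the predictor, so zero-noise scenarios admit exact
closed-loop identities — the package's primary oracle.

Defaults (the study conditions): 123 RILs × 315 SNPs on 12 chromosomes,
F₈ after 7 selfing generations with Haldane-map recombination; two
environments at 36.01 °N sown 2014-04-22 and 2015-05-19 (a ~1-month
shift); a 112-line panel across 8 synthetic site-years (33.6–39.5 °N,
April–June sowings) for the heading-date model.  Each growth trait has a
10-locus additive architecture with h² = 0.8 partitioning line-level
variance into a genetic part and an independent per-environment residual.
(α, β_P, G) are additive in the six heading-gene loci with means
(1.5, 2.0, 65) and SDs (0.3, 0.6, 7), chosen so heading falls 85–110 days
after sowing at 36 °N — the realistic range for japonica.  Weather is a
seasonal sinusoid plus AR(1) noise for temperature and a clipped sinusoid
for PAR; observed heading carries ±1-day rounding noise; leaf/tiller
observations follow an 11/5-date seasonal schedule with small Gaussian
noise.

Observed biomass is true simulated biomass times log-normal noise with
log-SD 0.12, which makes the realized GBLUP heritability of biomass
≈ 0.34 — deliberately low relative to the trait heritabilities, the
regime in which routing prediction through intermediate traits pays off.
Noise is multiplicative because biomass is positive and seasonal effects
act proportionally (τ is itself multiplicative); an additive variant can
be obtained by setting the sigma to zero and perturbing downstream.

What the generator does **not** emulate: selection during RIL
construction, segregation distortion, G×E of the CGM constants (IRUE, k),
spatial field trends, measurement error in weather, or epistasis.
Passing tests therefore demonstrate internal consistency and statistical
behavior of the machinery at realistic scale — not field-data accuracy.

## Problem sizes used in the shipped checks

Unit and property tests run at toy scale (tens of lines).  The
integrated-model comparison uses the default 123-line scenario with 20 CV
replicates; PSO recovery uses 20 panel lines × 8 trials (noiseless and
±2-day-rounded); heritability recovery uses 500 lines × 20 replicates.
`scripts/acceptance.py` re-runs the same computations at slightly reduced
replicate counts (10 CV replicates, 12 PSO lines) and reports every
quantity it prints from the run itself.

## Known limitations

- Eq-level constants (IRUE, k, β_leaf, S, 630 °C·d, the 800 °C·d tiller
  threshold, cardinal temperatures/photoperiods) are fixed, not fitted;
  τ is the only biomass-side free parameter.
- The DVR parameter map sees only six loci; heading variation from other
  genes is invisible to it (the direct-GP heading fallback exists for
  that case).
- PSO is stochastic; fits are reproducible only through the seeded RNG.
- The CGM has no water/nitrogen stress, respiration, or partitioning;
  predictions are potential-growth-shaped, with τ absorbing the rest.
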