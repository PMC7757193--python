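# Methods

## The model

`metaspom` implements a stochastic patch-occupancy model (SPOM) for a
three-species metacommunity module — a butterfly (M), its specialist
parasitoid wasp (C), and a powdery mildew (P) infecting the butterfly's
host plant — on a fixed network of habitat patches surveyed once per year.

Per-patch presence/absence evolves by yearly colonization and extinction.
For species *Y*, conditional on absence in year *t−1*, the colonization
probability in patch *i* is

    logit c_it = β₀ + Σ_j β_j x_ijt + γ_year[t] + γ_patch[i]

and symmetrically for the extinction probability conditional on presence.
Patch and year enter as crossed Gaussian random intercepts with variances
σ²_patch and σ²_year.  Covariates are the patch's host-plant
(*Plantago lanceolata*) cover as log(cover+1) (m²), the ordinal
*Veronica spicata* score 0–3 (butterfly and parasitoid models only), the
road-border flag, log monthly precipitation (May–August, selected by AIC
over all 2⁴ subsets), species-specific connectivity, and (mildew only)
host-plant connectivity.

Connectivity follows a negative-exponential dispersal kernel:

    S_it = Σ_{j≠i} exp(−α d_ij) · A_j · O_{j,t−1}

with d_ij the centroid Euclidean distance (km), A_j the patch area (m²)
and O the previous-year occupancy; the kernel scale defaults to
α = 1 km⁻¹ (mean dispersal distance 1 km, consistent with mark–recapture
estimates for all three species in this system).  Host connectivity
S^PL replaces A_j·O by the time-averaged host-plant cover and is
time-invariant.  Unsurveyed neighbours contribute zero to the sums;
missing cover years are imputed with the patch mean.

The parasitoid is hierarchically constrained: it cannot occur without the
butterfly.  Its colonization risk set comprises host-occupied patches plus
joint host–parasitoid arrivals, and its "extinctions" include losses
caused by host extinction — the same conflation present in the field
protocol this emulates, which matters for interpretation (see
*Limitations*).

Co-occurrence effects are screened by adding the previous-year patch state
(one of the six valid labels 0, M, MC, P, MP, MCP) as a fixed factor,
restricted to the levels compatible with each response (a species can only
colonize states where it is absent).  Support is the AIC difference
against the otherwise identical base model refitted to the identical rows;
negative ΔAIC favours the state model.  Per-state rates are reported as
inverse-logit transformed linear predictors at the environmental-covariate
means, with normal logit-scale intervals transformed to the rate scale (so
bounds always bracket the point estimate).

## Estimation

Fitting maximises the Laplace approximation to the marginal likelihood of
the binomial-logit GLMM.  For fixed variance components, the joint
penalised mode over (β, u_year, u_patch) is found by Newton iteration with
step halving; because no two patches share an observation row, the patch
block of the negative Hessian is diagonal, and each Newton step reduces to
a dense solve of dimension p + n_years after eliminating the patch block.
The two variance components are then profiled on the log-σ scale by
Nelder–Mead (β is profiled through the joint mode, as in lme4's
nAGQ = 1 scheme), which needs far fewer marginal-likelihood evaluations
than a joint quasi-Newton over (β, log σ) and keeps each fit in the order
of a second at 500 patches × 19 years.  Agreement with `lme4::glmer` on
shared data is at the 1e−3 level for the log-likelihood and ~1e−2 for
coefficients (exercised in the test suite).

Numerical choices:

* inner Newton convergence at gradient ∞-norm < 1e−5 (hard failure above
  1e−3 after 80 iterations);
* σ start value 0.3; log σ clipped to [−10, 4] (the lower bound is the
  plain-logistic limit to machine precision);
* quasi-separation (any |β| > 15 during optimisation) triggers one refit
  with a weak ridge (precision 1e−4) on the slopes and a warning;
* the fixed-effect covariance is the β-block of the inverse joint negative
  Hessian;
* AIC counts the fixed effects plus the two free variance components;
* fitting is fully deterministic given the data.

A variance component may be fixed (0 removes the factor); with both fixed
at zero the reported likelihood is the exact binomial log-likelihood,
which the test suite checks against an independent Newton–Raphson logistic
oracle.  Variance explained follows the latent-scale marginal/conditional
r² decomposition with logistic residual variance π²/3; per-covariate
shares are β_j²·Var(x_j) normalised by their sum (between-term covariances
are not apportioned).

## Forecasting and simulation

One-step-ahead occurrence probabilities use
p_it = o_{t−1}(1−e_it) + (1−o_{t−1})c_it with o the observed previous-year
state.  Parameter uncertainty is propagated by drawing the fixed effects
of all six models from their multivariate-normal sampling distributions
(default B = 1,000 draws; non-PSD covariances are repaired by clipping
negative eigenvalues, with a warning); observation uncertainty by one
Bernoulli realisation per patch-year per draw.  Random-effect modes are
held at their estimates rather than resampled — a documented, switchable
simplification; prediction intervals are 2.5/97.5 percentiles.  Community
draws enforce the hierarchy: a butterfly extinction removes the
parasitoid; a butterfly colonization admits it with its estimated
colonization probability; a persisting host lets it survive (1−e) or
colonize (c).

The closed-loop simulator propagates binary states (not probabilities):
each year it recomputes connectivity from the previous simulated year,
evaluates the rates, draws Bernoulli outcomes, and applies the same
community constraints.  Binary propagation keeps the state space
well-defined for the connectivity recomputation.  Year random effects for
simulated years are drawn fresh from N(0, σ²_year) per replicate; patch
effects stay at their conditional modes.  Ensembles default to R = 100
replicates with per-year 2.5/50/97.5 summaries of occupied fractions and
six-state counts.  Covariates for simulated years come from the supplied
tables by calendar year; years beyond the tables raise rather than
extrapolate or recycle.

Summaries are grouped per year or along the host-plant cover gradient in
k = 15 equal-count (quantile) classes of time-averaged cover — equal patch
counts, not equal cover widths, so every class is estimated from the same
number of patches.

## The synthetic-data generator

The generator emulates the structure of the Åland-type system at
configurable size.  Defaults:

* 500 patches in a 50 × 70 km extent, scattered around ~33 uniformly
  placed cluster centres (normal offsets, sd 0.8 km) — clustering creates
  the connectivity contrasts the kernel responds to;
* log-normal areas (median 30 m²); zero-inflated log-normal yearly cover
  (patch base × shared year factor × noise, ~8% zero patch-years,
  long-term mean near 8 m²); *V. spicata* scores concentrated in the
  western third of the extent; 30% road-bordering patches;
* May–August precipitation, log-normal around monthly means of 44–70 mm
  with a year-level factor (sd 0.25 on the log scale);
* 19 survey years, matching the study span.

Occupancy histories are produced by the simulator itself under a known
parameter set: initial butterfly occupancy 18%, parasitoid on 35% of
butterfly patches, mildew 10%, then 18 years of SPOM dynamics.  Slope
magnitudes follow the ordering estimated in the real system; intercepts
were calibrated once so that turnover rates land near the observed ranges
(colonization ~4–11% and extinction ~25–48% of possible events across
seeds, with all species persisting).  The parasitoid's extinction rate
sits slightly below the real system's 71% because that rate drives the
small synthetic parasitoid population to frequent global extinction;
persistence was prioritised so downstream fits stay well conditioned.
The `tiny` profile (20 patches × 5 years) uses denser initial occupancy
(60/50/40%) for the same reason.  An optional setting marks a fraction of
patch-years as unsurveyed (all species at once) to exercise the
missing-data paths.

What the generator does **not** emulate: the real spatial configuration of
Åland, observation/detection error (surveys are assumed exhaustive, as in
the source analyses), abundance dynamics, temporal trends in cover beyond
a stationary year factor, and any genotype-level plant–pathogen
specificity.  Passing recovery tests therefore demonstrates the
pipeline's internal consistency — that it estimates without systematic
bias the process it assumes — not the correctness of those assumptions
for field data.

## Validation problem sizes

The validation module re-runs the pipeline at these sizes (chosen as a
practical balance between Monte-Carlo error and turnaround):

* connectivity oracle: 100 random networks of ≤ 10 patches, double-loop
  summation, 1e−12 relative tolerance;
* logistic limit: 2,000 rows, every patch/year its own level;
* parameter recovery and forecast coverage: 20 replicate landscapes at
  500 patches × 19 years, B = 1,000 bootstrap draws; bias is summarised as
  the mean absolute relative bias of the seed-averaged butterfly and
  mildew coefficients with |β| ≥ 0.3 (per-coefficient checks at 20 seeds
  are dominated by Monte-Carlo noise: weather slopes carry only 18
  year-levels of information);
* stationarity: 200 decoupled patches × 500 years (burn-in 100) against
  the two-state chain closed form c/(c+e);
* patch-state screen: 20 null runs at 500 × 19 and 20 interaction runs
  (+0.7 log-odds mildew → butterfly colonization) at 2,000 × 15.

## Limitations

* Parasitoid parameters are not identified as "own-process" rates: joint
  colonizations and host-driven extinctions are mixed into its transition
  rows, exactly as in the emulated survey design.  Recovery checks
  therefore exclude the parasitoid models; its fits are still used (and
  constraint-checked) in all community-level predictions.
* The Laplace approximation can bias variance components at very small
  cluster sizes; fixed effects were verified unbiased at the default
  scales.
* The ΔAIC state screen is a heuristic: with one added dummy, ΔAIC < −2
  corresponds to a likelihood-ratio p ≈ 0.05, and its realised null rate
  (a few percent to ~20%) is documented by the calibration run, not
  asserted to a fixed value.
* Forecast intervals include Bernoulli observation noise, so their
  realised coverage of yearly occupied counts tends to sit above the
  nominal 95%.
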