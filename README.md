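# metaspom

Stochastic patch-occupancy modelling (SPOM) of interacting metapopulations:
a pipeline for multi-year presence/absence surveys of several interacting
species sharing a network of habitat patches — here a butterfly (M), its
specialist parasitoid wasp (C), and a powdery mildew (P) on the
butterfly's host plant.

The package is aimed at landscape ecologists and biostatisticians who want
to ask, from co-occurrence time series alone, whether species interactions
leave a detectable footprint in metacommunity dynamics — and to know how
well such a pipeline can recover the truth when the truth is known.

## What it does

1. **Connectivity** (`metaspom.landscape`).  Species-specific patch
   connectivity from a negative-exponential dispersal kernel,
   S_it = Σ_{j≠i} e^(−α·d_ij) · A_j · O_{j,t−1}, with α = 1 km⁻¹ by
   default (mean dispersal distance 1/α = 1 km), plus a time-invariant
   host-plant connectivity against mean cover.  Also: turnover-event
   assignment (colonizations/extinctions with possible-event
   denominators), the six-state patch encoding (0, M, MC, P, MP, MCP under
   the constraint that the parasitoid needs its host), and equal-count
   cover classes.
2. **Colonization/extinction models** (`metaspom.occmodels`).  Binomial
   GLMMs on the logit scale with crossed patch and year random intercepts,
   fitted by an in-package Laplace engine (validated against
   `lme4::glmer`); AIC selection over all 2⁴ subsets of May–August
   precipitation; marginal/conditional r² on the latent scale;
   per-covariate variance shares β_j²σ²(x_j); previous-year patch state as
   a fixed factor with ΔAIC screening and inverse-logit rate tables.
3. **Forecasting** (`metaspom.forecast`).  One-step-ahead occurrence
   probabilities p_it = o_{t−1}(1−e) + (1−o_{t−1})c with 95% prediction
   intervals from 1,000 parametric-bootstrap draws and Bernoulli
   observation draws, community-assembled under the host constraint.
4. **Simulation** (`metaspom.simulator`).  Closed-loop multi-year
   metacommunity simulation (default 100 replicates) that recomputes
   connectivity from the simulated occupancy each year.
5. **Synthetic data** (`metaspom.synthetic_data`).  Landscapes, weather,
   and ground-truth occupancy histories generated by the same process the
   pipeline fits, so every stage can be tested against known parameters.

A `metaspom` command-line tool exposes the stages (`synth`, `events`,
`fit`, `forecast`, `simulate`, `run`).

## Worked example

```python
from metaspom import synthetic_data as sd, landscape as lsc, occmodels as om

land, hist, precip, truth = sd.make_fixture("default", seed=1)

ev = lsc.assign_turnover_events(hist, "M")
print(f"butterfly: {len(ev.colonizations)} colonizations "
      f"({100*ev.col_rate:.1f}% of possible), "
      f"{len(ev.extinctions)} extinctions ({100*ev.ext_rate:.1f}%)")

tab = om.build_transition_table(hist, land, precip, "M", "colonization")
ranking, fit = om.select_weather_model(om.default_spec("M", "colonization"), tab)
print("weather subset selected:", ranking.iloc[0]["subset"])
print(fit.beta.round(3))
```

prints

```
butterfly: 543 colonizations (7.2% of possible), 565 extinctions (39.5%)
weather subset selected: precip_june
intercept     -6.904
log_cover      0.581
vs             0.365
conn           0.012
road           0.371
precip_june    0.614
```

The synthetic butterfly colonizes 7.2% of the patch-years in which it
could (and goes extinct from 39.5%), close to the generating regime.  The
fitted slopes are on the covariate scales (log m² cover, ordinal score,
raw connectivity, 0/1 road, log mm rain): more host plant, better
connectivity and a road border all raise colonization odds.  The selected
June term stands in for the correlated wet-spring signal the truth puts on
May — months share a year-level factor, so AIC may pick a correlated
proxy.  Screening the previous-year patch state on top of this model:

```python
sfit = om.fit_state_model(
    om.default_spec("M", "colonization", precip=("precip_may",)).with_state(), tab)
base = om.fit_occupancy_glmm(
    om.default_spec("M", "colonization", precip=("precip_may",)),
    tab.loc[sfit.row_index])
print(om.state_rates(sfit).round(2))
print(f"delta AIC (state vs base): {om.delta_aic(sfit, base):.1f}")
```

```
   rate    lo    hi
0  5.11  4.36  5.99
P  5.85  4.26  7.98
delta AIC (state vs base): 1.2
```

Colonization rates into empty (0) versus mildew-occupied (P) patches are
statistically indistinguishable and ΔAIC > 0: correctly no support for an
interaction, since this fixture was generated with independent species.

The same pipeline end to end, from the shell:

```sh
metaspom run --profile tiny --seed 4 --draws 100 --replicates 20 --out out/
```

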