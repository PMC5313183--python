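# burnprob

Stochastic burn-probability simulation and factor-contribution analysis
for human-dominated fire regimes.

## The problem

In subtropical mountain forests with strong human disturbance, nearly
all wildfires are started by people, most burn only a few hectares, and
suppression — not fuel exhaustion — ends them.  Fuel type, topography
and human access each shape the fire regime, but they do not shape
every regime attribute equally: the factors that best explain *where a
single fire starts* or *how large it grows* need not be the ones that
best explain the *annual burn probability* (BP) of a place, because BP
integrates thousands of overlapping ignition-and-spread events and can
amplify a spatially coherent driver.  `burnprob` implements the full
chain needed to measure that difference:

1. **Ignition occurrence** — binary logistic regression of fire /
   non-fire days and places, with mean-nearest-neighbor-distance
   pseudo-absence sampling, a |r| > 0.4 collinearity screen, Cox &
   Snell / Nagelkerke pseudo-R² and ROC AUC;
2. **Fire size** — an ensemble of 10 random forests (1000 trees,
   independent 2/3 subsamples, pooled out-of-bag residuals) with
   %IncMSE permutation importance;
3. **Burn probability** — Monte Carlo fire years: monthly Poisson
   ignition counts, acceptance–rejection placement on the day's
   ignition-probability surface, weather drawn from a ±10-day archive
   window, spread by a cellular automaton under the surface-fire rate
   model `R = R0·Kf·Kw·Kt` with `R0 = aT + bv + c(1−h) − d`
   (`a,b,c,d = 0.03, 0.05, 0.01, 0.3`), `Kw = exp(0.1783 v)`,
   `Kt = exp(3.533 tan(φ)^1.2)`, terminated at a stochastically drawn
   target size;
4. **Factor contribution** — OLS of log BP on the landscape layers and
   an exact lmg (Shapley) decomposition of R² into per-variable and
   per-group (fuel / topography / human) shares.

Because forest-survey and fire-registry data of this kind are not
redistributable, the package includes a synthetic-world generator
(`burnprob.synth`) that reproduces the statistical structure such an
analysis relies on — a fragmented four-type fuel mosaic tied to
elevation, a valley-following road with settlements, a 20-year daily
weather archive with a winter–spring fire season, and a fire history
produced by the same ignition + spread machinery with known parameters
— so every stage is testable against ground truth.  See
`docs/methods.md` for the models, assumptions and limitations.

## Worked example

```python
from burnprob.pipeline import reversal_experiment

out = reversal_experiment(seed=1, n_runs=1000)
print(f"occurrence: AUC {out['auc']:.3f}, first group by odds = {out['occurrence_first']}")
print(f"size: top %IncMSE group = {out['size_top_group']}, obs-pred r = {out['size_obs_pred_corr']:.2f}")
print("BP groups (lmg shares): "
      + ", ".join(f"{k}={float(v):.3f}" for k, v in out['group_shares'].items()))
print(f"reversal recovered: {out['reversal']}")
```

prints

```
occurrence: AUC 0.874, first group by odds = fuel
size: top %IncMSE group = fuel, obs-pred r = 0.62
BP groups (lmg shares): human=0.158, fuel=0.096, topography=0.027
reversal recovered: True
```

Reading it: on a synthetic world whose ignition surface carries a
dominant human-access gradient, the fitted occurrence model still ranks
fuel first by per-unit odds (pine/fir shares carry the largest
coefficients), and pine share tops the size importances — but once
10,000+ simulated fires are stacked into a burn-probability map, the
human-activity group (distance to road) explains the largest share of
log-BP variance.  That rank reversal between single-event attributes
and BP is the package's headline, and it is recovered in ≥ 8 of 10
seeds by the acceptance suite.

The same chain is available from the shell:

```sh
burnprob run-all --seed 1 --runs 1000 --out out/     # all stages + manifest
burnprob synth --seed 1 --out world/                 # just the synthetic world
burnprob fit-ignition --fires world/fires.csv --landscape world/landscape \
        --weather world/weather.csv --out fits/
burnprob importance --bp out/bp.asc --landscape out/landscape
burnprob validate --hist out/fires.csv --sim out/sim_fires.csv --years 20 --runs 1000
```

Rasters are Esri ASCII grids, tables are CSV, configs are YAML; every
`run-all` output directory carries a manifest with the seed and config
hash, and identical seeds give byte-identical outputs.

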