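# mortset

Trimmed forecast combination for age-specific mortality.

Pension funds and life insurers need accurate forecasts of old-age
mortality rates, and many stochastic mortality models compete for the
job — Lee-Carter and its adjustments, the Poisson generalized
age-period-cohort (GAPC) family (Renshaw-Haberman, age-period-cohort,
Cairns-Blake-Dowd and its M6/M7/M8 extensions, Plat), and functional
time-series models. No single model wins everywhere. `mortset`
implements a model-averaging strategy that, instead of estimating
combination weights, *trims* the pool: it scores every model's
expanding-window forecasts on a validation period, runs the model
confidence set (MCS) procedure to find the subset of models with
statistically indistinguishable predictive ability, and combines the
survivors' point and interval forecasts with equal weights. An
inverse-validation-error weighting of all models is included as the
baseline combiner.

## The method

Central death rates `m[x, t] = d[x, t] / e[x, t]` on an age × year grid
(ages 60…100+, the retirement range) are modeled on the log scale. The
pool spans three families:

* **Lee-Carter (Gaussian):** `ln m[x, t] = α_x + β_x κ_t + ε[x, t]`,
  with `Σ β_x = 1`, `Σ κ_t = 0`, `(β, κ)` from the leading singular pair
  of the centred log rates; variants re-solve `κ_t` against total
  deaths, the age distribution of deaths, or period life expectancy.
* **Poisson GAPC:** `d[x, t] ~ Poisson(e[x, t] exp(η[x, t]))` with
  `η[x, t] = α_x + Σ_i f_i(x) κ_t^{(i)} + g(x) γ_{t−x}`, fitted by
  alternating Newton updates and identified by the family's constraint
  transformations.
* **Functional time series:** penalized-spline-smoothed log-mortality
  curves decomposed by (robust) functional principal components,
  including coherent two-population variants (product-ratio,
  multivariate stacking, multilevel common/specific trends).

Period indexes are extrapolated by a (multivariate) random walk with
drift; cohort indexes by an AIC-selected ARIMA. Interval forecasts use
`var[ln m[x, n+h]] ≈ b_x² u_{n+h|n} + v_x` (score-forecast variance plus
residual variance) for the Gaussian/functional models and simulated
index paths for the GAPC family.

Forecast accuracy is measured per forecast curve by

* RMSFE: `sqrt(mean_x (y − ŷ)²)` over the k ages, and
* the mean interval score
  `S_α = (u − l) + (2/α)(l − y)·1{y<l} + (2/α)(y − u)·1{y>u}`
  averaged over ages, with `α = 0.2` (80% intervals).

Given the N × m validation loss matrix, the MCS procedure tests the
equal-predictive-ability hypothesis with studentized statistics
`T_R = max |t_ρξ|` or `T_max = max t_ρ·` (variances from a moving-block
bootstrap whose block length comes from AR fits to the loss
differentials), eliminates the worst model while the test rejects, and
returns the superior set at confidence level 1 − α (α = 0.10). Models
retained get weight `1/|superior set|`; trimmed models get zero.

## Worked example

No external data is needed: the package ships a synthetic-data
generator that emulates a two-sex retirement-age mortality panel
(41 ages × 41 years, Poisson death counts, correlated declining
trends).

```python
import mortset as ms

truth = ms.GroundTruth(seed=42, sex_gap=0.35)
popset = ms.simulate_population_set(truth, n_pops=2, cross_corr=0.8)

plan = ms.SplitPlan(train_end=1995, validation_end=2005, test_end=2015)
pool = {label: ms.make_model(label) for label in (1, 4, 9, 12, 13, 15)}
results = ms.expanding_window(popset, pool, plan, seed=42, population="F")

val_losses = ms.build_loss_matrix(results, popset["F"], "RMSFE",
                                  years=plan.validation_years())
mcs = ms.run_mcs(val_losses, alpha=0.10, statistic="T_max", B=1000, seed=42)
print("superior set:", [ms.model_name(m) for m in mcs.superior])

weights = ms.equal_weights(mcs, all_models=val_losses.models)
combined = ms.combine_window_results(results, weights)
test_losses = ms.build_loss_matrix({**results, "combined": combined},
                                   popset["F"], "RMSFE", years=plan.test_years())
for model, mean in zip(test_losses.models, test_losses.losses.mean(axis=0)):
    print(model, round(100 * mean, 2))
```

Output:

```
superior set: ['LC-Poisson', 'CBD', 'LC-total-deaths', 'LC-no-adjustment', 'FDM']
            LC-Poisson  test RMSFE x100 = 19.94
                   CBD  test RMSFE x100 = 20.64
       LC-total-deaths  test RMSFE x100 = 20.20
      LC-no-adjustment  test RMSFE x100 = 20.31
                   FDM  test RMSFE x100 = 21.42
         Product-ratio  test RMSFE x100 = 21.39
              combined  test RMSFE x100 = 19.77
```

The MCS trims the product-ratio model (step p-value 0.068 < 0.10) and
equally averages the five survivors; on the held-out test decade the
combined forecast (RMSFE × 100 = 19.77) beats every individual model.
The RMSFE here is on the log-rate scale and multiplied by 100.

The same flow is available from the shell: `mortset simulate` writes a
fixture, `mortset run --config config.yaml` executes the full
experiment (validation losses → MCS → combiners → test losses) and
writes CSV/JSON artifacts; `mortset fit`, `mortset evaluate`,
`mortset mcs`, and `mortset combine` expose the individual stages.

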