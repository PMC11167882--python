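# carboxkin

Kinetic modelling and bioprocess accounting for anaerobic **carboxylate
platform / chain-elongation** fermentations — the processes that turn ensiled
plant residues (sugar beet leaves, cassava leaves, *Elodea*/wheat straw) into
short- and medium-chain carboxylates (MCC: caproate C6, enanthate C7,
caprylate C8) using lactate and ethanol already present in the silage as
electron donors.

It is written for fermentation scientists who have carboxylate concentration
time series from batch bottles or semi-continuous stirred-tank reactors (STRs)
and want to (1) characterise the production kinetics — in particular the lag
phase before chain elongation starts — and (2) account for what the process
achieved in yields, selectivities and productivities.

## What it computes

**Kinetics.** Four product-formation models for the concentration ρ(t) (g/L)
of one carboxylate:

| model             | form                                                                   | parameters |
|-------------------|------------------------------------------------------------------------|-----------|
| first-order       | ρ(t) = ρ_max (1 − e^{−kt})                                             | ρ_max, k |
| modified Gompertz | ρ(t) = ρ_max exp(−exp((R_max e/ρ_max)(λ − t) + 1))                     | ρ_max, R_max, λ |
| Logistic          | ρ(t) = ρ_max / (1 + exp(4R_max(λ − t)/ρ_max + 2))                      | ρ_max, R_max, λ |
| Fitzhugh          | ρ(t) = ρ_max (1 − e^{−kt})^n                                           | ρ_max, k, n |

ρ_max is the plateau concentration (g/L), k a rate constant (1/d), R_max the
maximum production rate (g/L/d, the inflection slope), λ the lag phase (d),
and n a dimensionless shape constant (n = 1 reduces Fitzhugh to first-order;
n > 1 signals a lag phase). Models are fitted by bounded multi-start
nonlinear least squares (Latin-hypercube starts, deterministic per seed) and
ranked by

AIC = N ln(ss/N) + 2v,  RMSE = √(ss/N),  R² = 1 − ss/SS_tot,

where N is the number of pooled replicate observations, ss the residual sum
of squares and v the parameter count (2 or 3).

**Accounting.** Headspace gas moles from manometer readings via the ideal
gas law (n(x_i) [mmol] = P_abs·(x_i/100)·V_h / (R·T) · 1000, R = 83.140
mbar·L/(mol·K)); batch yield Y_P/S = ρ_P·V/m_S and STR yield Y_P/S = ρ_P·θ/m_S
(g per kgVS of substrate); selectivity S_P = 100·ρ_P/ρ_T; volumetric
productivity = yield·OLR/1000 (g/L/d); instantaneous selectivity
S_D/U = (k_D/k_U)·c^{α_D−α_U}; and MCC (C6–C8) aggregates.

**Synthetic data.** Because the study that motivated this package released
its result tables but not its raw time series, `carboxkin.simulate` generates
duplicate-bottle batch series (model curve + Gaussian noise, floored at zero)
and piecewise STR traces, and `run_recovery` quantifies whether a fitted
parameter could be recovered at all from a given design — bias and RMSE of
the estimator over many simulated datasets.

## Worked example

```python
from carboxkin import BatchSimConfig, FitConfig, fit_all
from carboxkin.datasets import KINETIC_FITS
from carboxkin.simulate import generate_batch_series

truth = KINETIC_FITS[("SBL", "C6", "gompertz")]   # caproate, sugar beet leaf silage
series = generate_batch_series(BatchSimConfig(truth=truth, noise_sigma=0.001, seed=42))
comparison = fit_all(series, FitConfig(seed=0))
```

Running `python examples/fit_kinetic_models.py` (which does exactly this and
prints the comparison) gives:

```
model              AIC    RMSE     R2  parameters
gompertz       -340.55  0.0007  0.999  rho_max=0.05008, R_max=0.00617, lag=7.19
fitzhugh       -333.03  0.0009  0.998  rho_max=0.05075, k=0.2973, n=20
logistic       -310.88  0.0014  0.996  rho_max=0.04909, R_max=0.006282, lag=7.489
first-order    -230.94  0.0075  0.876  rho_max=0.1014, k=0.026

best model by AIC: gompertz (fitted lag 7.19 d vs truth 7.02 d)
Fitzhugh shape constant n = 20.00 -> lag phase present
```

The modified Gompertz model wins the AIC ranking and recovers the ~7-day lag
phase typical of caproate formation with an un-adapted inoculum; the
lag-free first-order model is clearly rejected. The other scripts in
`examples/` each demonstrate one capability (batch and reactor accounting,
headspace gas moles, a disturbance trace, parameter recovery) and print a
line or two on what their numbers mean.

## Acceptance script

```sh
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

recomputes, from scratch, the two headline parameter-recovery quantities:
it simulates 50 noisy duplicate-bottle batch series from the published
modified-Gompertz caproate parameters for sugar-beet-leaf silage and 50 from
the published first-order propionate parameters for cassava-leaf silage,
refits each with the full multi-start pipeline, and writes the mean recovered
lag phase (d) and rate constant (1/d) as JSON. All randomness derives from
`--seed`.
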