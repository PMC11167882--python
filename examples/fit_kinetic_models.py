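"""Fit the four product-formation models to a lagged caproate series.

Simulates a duplicate-bottle batch fermentation in which caproate follows the
modified Gompertz curve published for sugar-beet-leaf silage (plateau
0.05 g/L, maximum rate 0.006 g/L/d, lag 7.02 d) with 0.001 g/L measurement
noise, fits all four kinetic models, and prints the AIC ranking: the
generating sigmoid should win, and the Fitzhugh shape constant should exceed
one, both signalling a lag phase.
"""

from carboxkin import BatchSimConfig, FitConfig, fit_all, lag_present
from carboxkin.datasets import KINETIC_FITS
from carboxkin.simulate import generate_batch_series

truth = KINETIC_FITS[("SBL", "C6", "gompertz")]
series = generate_batch_series(
    BatchSimConfig(truth=truth, noise_sigma=0.001, seed=42,
                   system_id="SBL", analyte="C6"))

comparison = fit_all(series, FitConfig(seed=0))

print(f"series: {series.system_id}/{series.analyte}, "
      f"N = {len(series)} points ({len(series.replicates)} replicates)")
print(f"{'model':<12} {'AIC':>9} {'RMSE':>7} {'R2':>6}  parameters")
for res in comparison.results:
    pars = ", ".join(f"{k}={v:.4g}" for k, v in vars(res.params).items())
    print(f"{res.model:<12} {res.aic:>9.2f} {res.rmse:>7.4f} {res.r2:>6.3f}  {pars}")

best = comparison.result_for(comparison.best)
fitz = comparison.result_for("fitzhugh")
print(f"\nbest model by AIC: {comparison.best} "
      f"(fitted lag {best.params.lag:.2f} d vs truth {truth.lag} d)")
print(f"Fitzhugh shape constant n = {fitz.params.n:.2f} -> "
      f"lag phase {'present' if lag_present(fitz.params) else 'absent'}")
print("\nLower AIC = better trade-off of fit quality against parameter count;"
      "\nthe recovered lag ~7 d matches caproate first appearing after day 7.")
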