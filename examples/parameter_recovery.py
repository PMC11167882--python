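"""Parameter-recovery simulation at a published ground truth.

Generates noisy duplicate-bottle caproate series from the modified Gompertz
parameters published for sugar-beet-leaf silage, refits the model to each,
and reports per-parameter bias and RMSE of the estimates — the check that
the fitting pipeline could have recovered the published lag phase had the
raw data been released.  (Uses 20 simulations to stay quick; the acceptance
script runs 50.)
"""

from carboxkin import BatchSimConfig, FitConfig, run_recovery
from carboxkin.datasets import KINETIC_FITS

truth = KINETIC_FITS[("SBL", "C6", "gompertz")]
sim = BatchSimConfig(truth=truth, noise_sigma=0.001, seed=2024)
report = run_recovery(sim, FitConfig(seed=1), n_sim=20)

print(f"model: {report.model}, {report.n_sim} simulations, "
      f"{report.n_failed} failed fits\n")
print(report.to_frame().to_string(index=False, float_format=lambda x: f"{x:.5f}"))
print("\nbias ~ 0 and small RMSE for the lag parameter mean the 7.02-day"
      "\nlag phase is recoverable from the 28-day duplicate-bottle design"
      "\nat realistic measurement noise.")
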