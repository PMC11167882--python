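# Methods

## Scope and shape

`carboxkin` reimplements, as a tested library, the quantitative analysis
layer of a chain-elongation fermentation study: lag-aware product-formation
kinetics with AIC-based model selection, and the deterministic bookkeeping
(gas moles, yields, selectivities, productivities) for batch serum bottles
and semi-continuously fed stirred-tank reactors. The package is a Python
library with narrative `examples/` scripts rather than a command-line tool:
its users work from notebooks and scripts, and every pipeline stage is a
plain function over plain data structures. File I/O (long-format series CSV,
gas-readings CSV, TSV report tables, flat key-value configs) lives in
`carboxkin.io`.

## Kinetic models

All four models describe a single analyte's concentration from inoculation
(t = 0) onward; none models substrate consumption or microbial growth, and
no ODEs are integrated — the forms are closed-form.

* **Fitzhugh bracketing.** The Fitzhugh form is implemented as
  ρ_max·(1 − e^{−kt})^n, the standard reading; it is the only bracketing
  under which n = 1 collapses to first-order and n > 1 produces the
  sigmoidal (lagged) start that the shape-constant interpretation relies on.
  `lag_present` applies the rule n > 1 strictly: n = 1 reports no lag.
* **Numerical safety.** The Gompertz double exponential is evaluated with
  the inner argument clipped at 30 (exp(30) already drives the result to an
  exact 0), and the Logistic form is routed through `scipy.special.expit`,
  so lag values far beyond the observation window cannot overflow.
* **`max_rate`** locates the supremum of dρ/dt numerically (second-order
  finite differences on a 2·10⁵-point grid spanning the transition region).
  For Gompertz/Logistic it reproduces the fitted R_max to well under 0.5%,
  which is the package's internal check that R_max really is the inflection
  slope. For Fitzhugh with n < 1 the true supremum is infinite (slope
  diverges at t = 0); the grid then returns a large finite value, documented
  as such.

## Fitting

* **Objective and optimizer.** Sum of squared residuals over all pooled
  replicate points, minimized by `scipy.optimize.least_squares`
  (trust-region reflective, bounded). The original analysis used a
  spreadsheet solver, which is single-start and irreproducible; here each
  fit runs `n_starts = 32` starting points — one data-driven heuristic
  (plateau ≈ max observation, lag ≈ first time above 5% of max, rate from
  the steepest finite-difference slope) plus Latin-hypercube samples of the
  bounded box, seeded — and keeps the lowest-SSE solution. Fits are
  bit-reproducible given (series, config).
* **Bounds.** ρ_max ∈ (10⁻⁶, 2·max obs], k ∈ (10⁻⁶, 20] /d,
  R_max ∈ (10⁻⁶, 10·max finite-difference slope], λ ∈ [0, max t],
  n ∈ (10⁻³, 20]; overridable per parameter via `FitConfig.bounds`. These
  enclose all published parameter estimates for these systems with wide
  margins. Note the ρ_max bound presumes the curve approaches its plateau
  within the observation window — see Limitations.
* **Parameter counts.** v = 2 (first-order) or 3 (others); ρ_max is always
  fitted, never pinned to the observed maximum.
* **Baseline.** Default fits the measured concentrations as-is
  (`baseline_mode="raw"`). Silage substrates carry carboxylates at t = 0,
  so `subtract_t0` (subtract the mean t = 0 concentration, floor at 0) is
  available where net production is wanted; the choice is the user's because
  the source analysis is silent on it.
* **Replicates** are pooled as individual residual points (no averaging, no
  mixed-effects structure): with duplicate bottles and homoscedastic noise,
  pooling is the maximum-likelihood treatment and keeps N honest in the AIC.
* **Statistics.** R² = 1 − ss/SS_tot about the observation mean (undefined,
  and raised as such, for zero-variance data); AIC = N ln(ss/N) + 2v; a
  perfect fit (ss = 0) maps AIC to −∞ with a warning instead of raising, so
  ranking still works — printed fit tables do contain RMSE = 0.000 cells.
  Ranking is ascending AIC, ties broken by RMSE, then parsimony (smaller v),
  then the canonical model order (first-order, Gompertz, Logistic, Fitzhugh).
  Models that cannot be fitted (too few points, degenerate series) are
  recorded as failed and rendered as "–" cells in the TSV report.

## Accounting

* **Gas moles.** n(x_i) [mmol] = P_abs·(x_i/100)·V_h/(R·T)·1000 with
  P_abs = gauge + 1013.25 mbar. The gas constant is implemented as
  R = 83.140 mbar·L/(mol·K) with V_h in litres: the commonly printed
  "mbar·cm³/(mol·K)" pairing of that numeral is dimensionally inconsistent
  with a mmol result for a 75-mL headspace, and the litre reading is the one
  that agrees with the SI ideal-gas computation (verified in tests to 1e-9
  relative). The ambient reference 1013.25 mbar is the standard atmosphere;
  bottles report gauge pressure only.
* **Yields.** Batch: Y = ρ_P·V/m_S with bottle working volume V = 0.125 L
  and m_S = 2.72 gVS of substrate by default. STR: Y = ρ_P·θ/m_S with daily
  harvest θ = 3 L and daily substrate mass m_S = OLR·V/1000 (default
  21.9 gVS/L/d · 12 L = 0.2628 kgVS/d).
* **Productivity** = yield·OLR/1000 (g/L/d). No closed formula was published
  for it; this relation regenerates 13 of the 14 published productivity
  cells to ±0.005 g/L/d (the remaining propionate cell disagrees in the
  source table itself and is treated as a documented discrepancy).
* **MCC aggregate** sums chain lengths 6–8 (caproate, enanthate, caprylate);
  valerate (C5) is excluded. Analyte labels are accepted as names or "C<n>";
  anything unmappable raises rather than being silently dropped.

## Synthetic data

The generator emulates the stated experimental world, not a tunable one:
duplicate bottles (`replicates = 2`), a 28-day incubation sampled at days
{0, 1, 3, 5, 7, 9, 11, 14, 17, 21, 24, 28} (the published design names the
28-day horizon and events at days 3, 7, 11, 21, 28; this grid covers them
with early-phase densification), additive homoscedastic Gaussian noise
truncated at zero. Only replicate standard deviations were published, so
Gaussian homoscedasticity is an assumption; the default σ for recovery
experiments is 2% of the ground-truth plateau, which keeps even the smallest
published caproate plateaus above the noise. The generator does **not**
emulate: heteroscedastic analytics, pH coupling, gas-production feedback,
substrate depletion, or community dynamics — so a green recovery test
establishes identifiability under idealized noise, not robustness to real
measurement pathology.

STR traces are piecewise saturating exponentials (contiguous phases, each
relaxing toward its plateau), sufficient to exercise the accounting layer on
rise–disturbance–recovery shapes; they are not a mechanistic reactor model.

## Known limitations

* **Plateau identifiability.** If a curve reaches only a small fraction of
  its plateau within the sampling window, ρ_max — and for Fitzhugh the
  (ρ_max, k, n) triple jointly — is not identifiable; estimates then sit on
  or near the ρ_max bound and the shape constant is biased upward. This is a
  property of the estimator and the design, not of the optimizer: the
  package's recovery harness makes it visible (one published Fitzhugh
  parameter set for caproate has exactly this character and its recovery
  check fails honestly at the 10% band). Extend the sampling horizon or fix
  ρ_max externally when the plateau is not observed.
* No parameter confidence intervals or bootstrap; point estimates only.
* No volatile-solids correction for ensiling losses, no COD/electron
  balances, no gas-volume normalization for flow counters.
* The significance comparison of rate constants across models reported in
  the source study is unspecified there and not implemented.
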