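"""Published reference values used as *inputs* by the examples, tests and
acceptance script.

These are the printed result tables of the sugar-beet-leaf / cassava-leaf /
Elodea+wheat-straw chain-elongation study this package reimplements the
analysis of: batch yield maxima after 21 days, semi-continuous (STR) yield
and productivity maxima for the un-enriched (E1) and enriched-inoculum (E2)
experiments, and the kinetic parameters estimated for carboxylate production
from the two leaf silages.  The study's raw time series are unpublished, so
these printed values are the only data-level anchors available; the kinetic
parameter sets double as ground truths for parameter-recovery simulations.
"""

from __future__ import annotations

from .models import FirstOrderParams, FitzhughParams, GompertzParams

__all__ = [
    "BATCH_YIELDS_21D",
    "STR_YIELDS",
    "STR_PRODUCTIVITIES",
    "STR_OLR",
    "BATCH_CAPROATE_MAX",
    "KINETIC_FITS",
]

#: Maximum batch carboxylate yields (g/kgVS) after 21 days, per substrate.
#: X+L = xylan+lactate standard, MS = maize silage, SBL = sugar beet leaf
#: silage, Cass = cassava leaf silage, Elo = Elodea/wheat straw silage.
BATCH_YIELDS_21D = {
    "X+L":  {"C2": 216.23, "C3": 46.55, "C4": 265.54, "C5": 4.85, "C6": 12.21},
    "MS":   {"C2": 258.69, "C3": 14.46, "C4": 78.69, "C5": 10.56, "C6": 21.03},
    "SBL":  {"C2": 303.56, "C3": 33.99, "C4": 24.89, "C5": 1.07, "C6": 1.97},
    "Cass": {"C2": 408.65, "C3": 30.97, "C4": 66.19, "C5": 8.80, "C6": 3.48},
    "Elo":  {"C2": 176.207, "C3": 10.11, "C4": 10.88, "C5": 3.27, "C6": 0.88},
}

#: Maximum product yields (g/kgVS) in the two semi-continuous STR trials.
STR_YIELDS = {
    "E1": {"acetate": 104.31, "propionate": 11.87, "butyrate": 38.62,
           "valerate": 6.27, "caproate": 42.74, "enanthate": 0.40,
           "caprylate": 0.17},
    "E2": {"acetate": 89.57, "propionate": 5.72, "butyrate": 37.82,
           "valerate": 8.17, "caproate": 60.92, "enanthate": 10.06,
           "caprylate": 22.69},
}

#: Printed productivities (g/L/d) for the same experiments; the E1 caprylate
#: cell was printed "negligible" and is recorded as 0.0.
STR_PRODUCTIVITIES = {
    "E1": {"acetate": 2.28, "propionate": 0.26, "butyrate": 0.85,
           "valerate": 0.14, "caproate": 0.94, "enanthate": 0.01,
           "caprylate": 0.0},
    "E2": {"acetate": 1.96, "propionate": 0.15, "butyrate": 0.83,
           "valerate": 0.18, "caproate": 1.33, "enanthate": 0.22,
           "caprylate": 0.50},
}

#: Organic loading rate of both STR trials, gVS/L/d.
STR_OLR = 21.9

#: Maximum caproate concentrations (g/L) observed in batch at day 21.
BATCH_CAPROATE_MAX = {"MS": 0.64, "Elo": 0.02, "SBL": 0.05, "Cass": 0.08, "X+L": 0.27}

#: Kinetic parameter point estimates for the leaf silages.  Plateau values
#: (rho_max) were not printed; they are taken as the stated observed maxima
#: (caproate) or back-computed from the batch yields via rho = Y·mS/V with
#: mS = 2.72 gVS and V = 0.125 L (propionate, butyrate).
KINETIC_FITS = {
    ("SBL", "C6", "gompertz"): GompertzParams(rho_max=0.05, R_max=0.006, lag=7.020),
    ("Cass", "C6", "gompertz"): GompertzParams(rho_max=0.08, R_max=0.005, lag=6.610),
    ("Cass", "C3", "first-order"): FirstOrderParams(rho_max=0.674, k=0.115),
    ("SBL", "C3", "first-order"): FirstOrderParams(rho_max=0.740, k=0.123),
    ("Cass", "C6", "fitzhugh"): FitzhughParams(rho_max=0.08, k=0.026, n=2.471),
    ("SBL", "C6", "fitzhugh"): FitzhughParams(rho_max=0.05, k=0.017, n=2.519),
    ("Cass", "C4", "first-order"): FirstOrderParams(rho_max=1.440, k=0.129),
}
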