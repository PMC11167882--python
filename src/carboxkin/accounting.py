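"""Bioprocess bookkeeping for batch bottles and semi-continuous stirred-tank
reactors (STRs): headspace gas moles, product yields, selectivities,
productivities and medium-chain-carboxylate (MCC) aggregates.

Conventions
-----------
* Gas amounts come from the ideal gas law applied to the bottle headspace:
  ``n(x_i) [mmol] = P_abs · (x_i/100) · V_h / (R·T) · 1000`` with the gauge
  reading converted to absolute pressure by adding one standard atmosphere
  (1013.25 mbar) and R = 83.140 mbar·L/(mol·K), V_h in litres.
* Batch yield:  Y_P/S = ρ_P · V / m_S            (g per kgVS fed)
* STR yield:    Y_P/S = ρ_P · θ / m_S            (θ = daily harvest volume, L)
* Selectivity:  S_P = 100 · ρ_P / ρ_T            (% of total carboxylates)
* Productivity: yield · OLR / 1000               (g/L/d; OLR in gVS/L/d)
* Instantaneous selectivity between a desired (D) and undesired (U) product:
  S_D/U = (k_D/k_U) · c^(α_D − α_U); for equal reaction orders it reduces to
  the ratio of the first-order rate constants.
* MCC = carboxylates with 6–8 carbons (caproate, enanthate, caprylate).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import pandas as pd

from .errors import DomainError, LabellingError, ValidationError

__all__ = [
    "STANDARD_ATMOSPHERE_MBAR",
    "GAS_CONSTANT_MBAR_L",
    "BatchBottleConfig",
    "ReactorConfig",
    "GasReading",
    "SelectivityQuery",
    "gas_moles",
    "batch_yield",
    "str_yield",
    "selectivity",
    "selectivity_table",
    "productivity",
    "instantaneous_selectivity",
    "chain_length",
    "mcc_aggregate",
    "yield_report",
]

#: Ambient reference added to gauge pressure, mbar.
STANDARD_ATMOSPHERE_MBAR = 1013.25
#: Universal gas constant in mbar·L/(mol·K).
GAS_CONSTANT_MBAR_L = 83.140


def _positive(name, value):
    if not value > 0:
        raise ValidationError(f"{name} must be > 0, got {value!r}")


@dataclass(frozen=True)
class BatchBottleConfig:
    """Serum-bottle geometry: working volume V and headspace V_h (L),
    substrate mass m_S (kgVS) and incubation temperature (K)."""

    working_volume: float = 0.125
    headspace_volume: float = 0.075
    substrate_mass: float = 0.00272
    temperature: float = 311.15

    def __post_init__(self):
        for f in ("working_volume", "headspace_volume", "substrate_mass", "temperature"):
            _positive(f, getattr(self, f))


@dataclass(frozen=True)
class ReactorConfig:
    """Semi-continuous STR constants: working volume (L), daily harvest
    volume θ (L/d), organic loading rate (gVS/L/d) and hydraulic retention
    time (d).  HRT must equal working_volume / θ."""

    working_volume: float = 12.0
    harvest_volume: float = 3.0
    olr: float = 21.9
    hrt: float = 4.0

    def __post_init__(self):
        for f in ("working_volume", "harvest_volume", "olr", "hrt"):
            _positive(f, getattr(self, f))
        if self.harvest_volume > self.working_volume:
            raise ValidationError("harvest volume cannot exceed working volume")
        if abs(self.hrt - self.working_volume / self.harvest_volume) > 1e-9:
            raise ValidationError("hrt must equal working_volume / harvest_volume")

    @property
    def daily_substrate_mass(self) -> float:
        """Substrate fed per day, kgVS (= OLR · V / 1000)."""
        return self.olr * self.working_volume / 1000.0


@dataclass(frozen=True)
class GasReading:
    """One headspace measurement: gauge pressure (mbar), one component's
    volume fraction (%) and gas temperature (K)."""

    gauge_pressure: float
    fraction_pct: float
    temperature: float
    component: str = ""

    def __post_init__(self):
        if not 0.0 <= self.fraction_pct <= 100.0:
            raise ValidationError("fraction must be within [0, 100] %")
        if self.absolute_pressure <= 0:
            raise ValidationError("absolute pressure must be > 0")
        if self.temperature <= 0:
            raise ValidationError("temperature must be > 0 K")

    @property
    def absolute_pressure(self) -> float:
        return self.gauge_pressure + STANDARD_ATMOSPHERE_MBAR


def gas_moles(reading: GasReading, headspace_volume: float) -> float:
    """Millimoles of one gas component in the bottle headspace (ideal gas)."""
    if headspace_volume <= 0:
        raise DomainError("headspace volume must be > 0 L")
    if reading.absolute_pressure <= 0 or reading.temperature <= 0:
        raise DomainError("absolute pressure and temperature must be > 0")
    return (reading.absolute_pressure * (reading.fraction_pct / 100.0)
            * headspace_volume
            / (GAS_CONSTANT_MBAR_L * reading.temperature) * 1000.0)


def batch_yield(rho_p: float, config: BatchBottleConfig) -> float:
    """Batch product yield ρ_P·V/m_S in g per kgVS of substrate fed."""
    if rho_p < 0:
        raise ValidationError("concentration must be >= 0")
    return rho_p * config.working_volume / config.substrate_mass


def str_yield(rho_p: float, harvest_volume: float, daily_substrate_mass: float) -> float:
    """STR product yield ρ_P·θ/m_S (g/kgVS) from the daily harvest volume θ
    (L) and the daily substrate feed m_S (kgVS)."""
    if rho_p < 0:
        raise ValidationError("concentration must be >= 0")
    _positive("harvest_volume", harvest_volume)
    _positive("daily_substrate_mass", daily_substrate_mass)
    return rho_p * harvest_volume / daily_substrate_mass


def selectivity(rho_p: float, rho_total: float) -> float:
    """Product share of the total carboxylate concentration, in %."""
    if rho_total <= 0:
        raise DomainError("total carboxylate concentration must be > 0")
    if not 0 <= rho_p <= rho_total:
        raise ValidationError("need 0 <= rho_p <= rho_total")
    return 100.0 * rho_p / rho_total


def selectivity_table(concentrations: Mapping[str, float]) -> dict:
    """Selectivities (%) for a closed product set; the values sum to 100."""
    total = sum(concentrations.values())
    return {a: selectivity(c, total) for a, c in concentrations.items()}


def productivity(yield_g_per_kgvs: float, olr: float) -> float:
    """Volumetric productivity (g/L/d) from a yield (g/kgVS) and the organic
    loading rate (gVS/L/d); the /1000 reconciles gVS with kgVS."""
    if yield_g_per_kgvs < 0 or olr < 0:
        raise ValidationError("yield and OLR must be >= 0")
    return yield_g_per_kgvs * olr / 1000.0


@dataclass(frozen=True)
class SelectivityQuery:
    """Rate constants (1/d), reaction orders and substrate concentration
    (g/L) for the instantaneous desired/undesired selectivity ratio."""

    k_desired: float
    k_undesired: float
    alpha_desired: float = 1.0
    alpha_undesired: float = 1.0
    substrate_concentration: float = 1.0

    def __post_init__(self):
        if self.k_undesired <= 0:
            raise DomainError("k_undesired must be > 0")
        if self.substrate_concentration <= 0:
            raise ValidationError("substrate concentration must be > 0")


def instantaneous_selectivity(query: SelectivityQuery) -> float:
    """S_D/U = (k_D/k_U)·c^(α_D−α_U); independent of c when the orders match."""
    return (query.k_desired / query.k_undesired
            * query.substrate_concentration
            ** (query.alpha_desired - query.alpha_undesired))


# ---------------------------------------------------------------------------
# Analyte labels and MCC aggregation
# ---------------------------------------------------------------------------

_CHAIN_LENGTHS = {
    "acetate": 2, "c2": 2,
    "propionate": 3, "c3": 3,
    "butyrate": 4, "c4": 4,
    "valerate": 5, "c5": 5,
    "caproate": 6, "c6": 6,
    "enanthate": 7, "heptanoate": 7, "c7": 7,
    "caprylate": 8, "octanoate": 8, "c8": 8,
}

#: MCC range: medium-chain carboxylates span 6 to 8 carbons here.
MCC_RANGE = (6, 8)


def chain_length(analyte: str) -> int:
    """Carbon chain length for a carboxylate label (name or 'C<n>' form)."""
    try:
        return _CHAIN_LENGTHS[analyte.strip().lower()]
    except KeyError:
        raise LabellingError(f"unknown analyte label {analyte!r}") from None


def mcc_aggregate(records: Mapping[str, float]) -> float:
    """Sum a per-analyte quantity (yield or productivity) over the
    medium-chain carboxylates C6–C8; an empty record set sums to 0."""
    lo, hi = MCC_RANGE
    return sum(v for a, v in records.items() if lo <= chain_length(a) <= hi)


def yield_report(yields: Mapping[str, float], olr: float) -> pd.DataFrame:
    """Per-analyte yield (g/kgVS) and productivity (g/L/d) table with an MCC
    total row, for semi-continuous runs."""
    rows = [
        {"analyte": a, "chain_length": chain_length(a),
         "yield_g_per_kgvs": y, "productivity_g_per_l_d": productivity(y, olr)}
        for a, y in yields.items()
    ]
    df = pd.DataFrame(rows)
    mcc_row = {
        "analyte": "MCC (C6-C8)", "chain_length": pd.NA,
        "yield_g_per_kgvs": mcc_aggregate(yields),
        "productivity_g_per_l_d": mcc_aggregate(
            {a: productivity(y, olr) for a, y in yields.items()}),
    }
    return pd.concat([df, pd.DataFrame([mcc_row])], ignore_index=True)
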