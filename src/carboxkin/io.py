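"""Tabular input/output: long-format concentration series (CSV), headspace
gas readings (CSV), flat key-value run configuration, and fit/yield report
tables (TSV).

The series schema is one observation per row with columns
``system_id, replicate, day, analyte, concentration`` — UTF-8, "." decimal
separator, header required.  Report tables print numbers at fixed 3-decimal
precision and mark unfittable cells with "–".
"""

from __future__ import annotations

from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .accounting import GasReading
from .errors import SchemaError, ValidationError
from .fitting import ModelComparison, TimeSeries
from .models import _PARAM_NAMES

__all__ = [
    "SERIES_COLUMNS",
    "read_series",
    "write_series",
    "read_gas_readings",
    "write_fit_table",
    "write_recovery_table",
    "read_config",
]

SERIES_COLUMNS = ("system_id", "replicate", "day", "analyte", "concentration")
_KEY = ["system_id", "replicate", "day", "analyte"]


def read_series(path) -> list[TimeSeries]:
    """Read a long-format series CSV into TimeSeries objects, one per
    (system_id, analyte) group, replicate labels preserved.

    Raises :class:`SchemaError` for missing columns or duplicated
    (system, replicate, day, analyte) keys, and :class:`ValidationError`
    (listing offending line numbers) for negative days or concentrations.
    """
    df = pd.read_csv(path)
    missing = [c for c in SERIES_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing column(s) {', '.join(missing)}")
    for col in ("day", "concentration"):
        df[col] = pd.to_numeric(df[col], errors="coerce")
        bad = df.index[df[col].isna() | (df[col] < 0)] + 2  # header + 1-based
        if len(bad):
            raise ValidationError(
                f"{path}: non-numeric or negative {col} on line(s) "
                f"{', '.join(map(str, bad.tolist()))}")
    dup = df.duplicated(subset=_KEY)
    if dup.any():
        lines = (df.index[dup] + 2).tolist()
        raise SchemaError(f"{path}: duplicate (system, replicate, day, analyte) "
                          f"key on line(s) {', '.join(map(str, lines))}")
    out = []
    for (sid, analyte), grp in df.groupby(["system_id", "analyte"], sort=True):
        pts = tuple(zip(grp["day"], grp["concentration"], grp["replicate"].astype(str)))
        out.append(TimeSeries(str(sid), str(analyte), pts))
    return out


def write_series(series_list: Iterable[TimeSeries], path) -> None:
    """Write TimeSeries objects back to the long-format CSV schema,
    preserving values to 12 significant digits."""
    rows = [
        {"system_id": s.system_id, "replicate": rep, "day": t,
         "analyte": s.analyte, "concentration": c}
        for s in series_list for (t, c, rep) in s.points
    ]
    pd.DataFrame(rows, columns=list(SERIES_COLUMNS)).to_csv(
        path, index=False, float_format="%.12g")


def read_gas_readings(path) -> list[GasReading]:
    """Read a gas-readings CSV with columns gauge_mbar, fraction_pct, temp_K
    and component."""
    df = pd.read_csv(path)
    required = ("gauge_mbar", "fraction_pct", "temp_K", "component")
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing column(s) {', '.join(missing)}")
    return [GasReading(gauge_pressure=row.gauge_mbar, fraction_pct=row.fraction_pct,
                       temperature=row.temp_K, component=str(row.component))
            for row in df.itertuples()]


_FIT_COLUMNS = ["system_id", "analyte", "model", "rho_max", "k", "R_max",
                "lambda", "n", "N", "v", "ss", "R2", "AIC", "RMSE", "converged"]
_DASH = "–"


def _fmt(value) -> str:
    if value is None:
        return _DASH
    if isinstance(value, str):
        return value
    if isinstance(value, bool):
        return str(value)
    if isinstance(value, (int, np.integer)):
        return str(int(value))
    if value == -np.inf:
        return "-inf"
    return f"{value:.3f}"


def write_fit_table(comparisons: Sequence[ModelComparison], path) -> None:
    """Write a per-model fit report TSV: one row per (series, model), with
    failed/unfitted models as rows of "–" cells; 3-decimal formatting."""
    lambda_name = {"lag": "lambda"}
    rows = []
    for comp in comparisons:
        fitted = {r.model: r for r in comp.results}
        for model in list(fitted) + list(comp.failed):
            row = {c: None for c in _FIT_COLUMNS}
            row.update(system_id=comp.system_id, analyte=comp.analyte, model=model)
            res = fitted.get(model)
            if res is not None:
                for pname in _PARAM_NAMES[model]:
                    row[lambda_name.get(pname, pname)] = getattr(res.params, pname)
                row.update(N=res.N, v=res.v, ss=res.ss, R2=res.r2,
                           AIC=res.aic, RMSE=res.rmse, converged=res.converged)
            rows.append(row)
    path = Path(path)
    with path.open("w", encoding="utf-8") as fh:
        fh.write("\t".join(_FIT_COLUMNS) + "\n")
        for row in rows:
            fh.write("\t".join(_fmt(row[c]) for c in _FIT_COLUMNS) + "\n")


def write_recovery_table(report, path) -> None:
    """Write a RecoveryReport summary as TSV (one row per parameter)."""
    report.to_frame().to_csv(path, sep="\t", index=False, float_format="%.6g")


def read_config(path) -> dict:
    """Read a flat ``key = value`` configuration file; values are parsed as
    float where possible, else kept as strings.  Lines starting with '#' and
    blank lines are ignored."""
    out = {}
    for i, raw in enumerate(Path(path).read_text(encoding="utf-8").splitlines(), 1):
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        if "=" not in line:
            raise SchemaError(f"{path}:{i}: expected 'key = value', got {raw!r}")
        key, _, value = line.partition("=")
        value = value.strip()
        try:
            out[key.strip()] = float(value)
        except ValueError:
            out[key.strip()] = value
    return out
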