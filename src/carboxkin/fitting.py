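"""Least-squares estimation of the kinetic models and AIC-based model ranking.

A :class:`TimeSeries` holds one analyte's pooled concentration trajectory
(replicate bottle points kept as individual observations).  Each model is fit
by bounded nonlinear least squares (scipy's trust-region-reflective solver)
from multiple Latin-hypercube starting points, which makes the optimisation
reproducible and robust to the multimodal SSE landscapes that sigmoids with a
lag parameter produce.  Candidate models are then ranked by the Akaike
Information Criterion

    AIC = N * ln(ss / N) + 2 v

with the root-mean-square error RMSE = sqrt(ss / N) and the coefficient of
determination R² = 1 − ss / SStot as secondary diagnostics, where N is the
number of observations, ss the residual sum of squares and v the number of
fitted parameters (2 for first-order, 3 for the others).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
from scipy.optimize import least_squares
from scipy.stats import qmc

from .errors import (
    DegenerateSeriesError,
    InsufficientDataError,
    MismatchError,
    NoFitError,
    UndefinedStatisticError,
    ValidationError,
)
from .models import (
    MODEL_ORDER,
    ModelParams,
    _PARAM_NAMES,
    eval_raw,
    params_to_vector,
    vector_to_params,
)

__all__ = [
    "TimeSeries",
    "FitConfig",
    "FitResult",
    "ModelComparison",
    "fit_model",
    "fit_all",
    "rank_models",
    "compute_r2",
    "compute_aic",
    "compute_rmse",
    "n_params",
]

#: Free parameters per model (rho_max is always fitted, never pinned).
_N_PARAMS = {"first-order": 2, "gompertz": 3, "logistic": 3, "fitzhugh": 3}


def n_params(model: str) -> int:
    """Number of fitted parameters v for a model name."""
    return _N_PARAMS[model]


@dataclass(frozen=True)
class TimeSeries:
    """One analyte's concentration trajectory for one system.

    ``points`` is a sequence of ``(t_days, concentration_g_per_L, replicate)``
    tuples; times need not be unique because replicate bottles are sampled on
    the same days.
    """

    system_id: str
    analyte: str
    points: tuple

    def __post_init__(self) -> None:
        pts = tuple((float(t), float(c), str(r)) for t, c, r in self.points)
        if not pts:
            raise ValidationError("TimeSeries needs at least one point")
        if any(t < 0 for t, _, _ in pts):
            raise ValidationError("times must be >= 0")
        if any(c < 0 for _, c, _ in pts):
            raise ValidationError("concentrations must be >= 0")
        object.__setattr__(self, "points", pts)

    @property
    def t(self) -> np.ndarray:
        return np.array([p[0] for p in self.points])

    @property
    def concentration(self) -> np.ndarray:
        return np.array([p[1] for p in self.points])

    @property
    def replicates(self) -> tuple:
        return tuple(sorted({p[2] for p in self.points}))

    def __len__(self) -> int:
        return len(self.points)

    @classmethod
    def from_arrays(cls, system_id, analyte, t, concentration, replicate=None):
        t = np.asarray(t, dtype=float)
        c = np.asarray(concentration, dtype=float)
        if replicate is None:
            replicate = np.array(["r1"] * len(t))
        rep = np.asarray(replicate)
        return cls(system_id, analyte, tuple(zip(t, c, rep)))


@dataclass(frozen=True)
class FitConfig:
    """Settings for one fit: number of multi-starts, RNG seed, optional
    per-parameter bound overrides, solver tolerance, baseline handling."""

    n_starts: int = 32
    seed: int = 0
    bounds: Mapping[str, tuple] | None = None
    sse_tol: float = 1e-12
    baseline_mode: str = "raw"  # or "subtract_t0"

    def __post_init__(self) -> None:
        if self.n_starts < 1:
            raise ValidationError("n_starts must be >= 1")
        if self.sse_tol <= 0:
            raise ValidationError("sse_tol must be > 0")
        if self.baseline_mode not in ("raw", "subtract_t0"):
            raise ValidationError(f"unknown baseline_mode {self.baseline_mode!r}")
        if self.bounds is not None:
            for name, (lo, hi) in self.bounds.items():
                if not lo < hi:
                    raise ValidationError(f"bounds for {name!r}: lower must be < upper")


@dataclass(frozen=True)
class FitResult:
    """Winning parameter set for one (series, model) pair with its statistics."""

    model: str
    params: ModelParams
    N: int
    v: int
    ss: float
    r2: float
    aic: float
    rmse: float
    converged: bool
    n_starts_used: int
    system_id: str = ""
    analyte: str = ""

    def __post_init__(self) -> None:
        if self.ss < 0:
            raise ValidationError("ss must be >= 0")
        if self.N <= self.v:
            raise ValidationError("N must exceed the number of parameters v")
        if not math.isclose(self.rmse, math.sqrt(self.ss / self.N),
                            rel_tol=1e-12, abs_tol=1e-300):
            raise ValidationError("rmse must equal sqrt(ss/N)")


@dataclass(frozen=True)
class ModelComparison:
    """Fit results for all attempted models on one series, ranked by AIC."""

    results: tuple            # successful FitResults, ranked best-first
    ranking: tuple            # model names, best first
    best: str
    failed: Mapping[str, str] = field(default_factory=dict)  # model -> reason
    system_id: str = ""
    analyte: str = ""

    def __post_init__(self) -> None:
        if tuple(r.model for r in self.results) != tuple(self.ranking):
            raise ValidationError("ranking must order the fitted results")
        if self.ranking and self.best != self.ranking[0]:
            raise ValidationError("best must be ranking[0]")

    def result_for(self, model: str) -> FitResult:
        for r in self.results:
            if r.model == model:
                return r
        raise KeyError(model)


# ---------------------------------------------------------------------------
# Goodness-of-fit statistics
# ---------------------------------------------------------------------------

def compute_rmse(N: int, ss: float) -> float:
    """Root-mean-square error sqrt(ss/N) in g/L."""
    if N <= 0:
        raise ValidationError("N must be > 0")
    if ss < 0:
        raise ValidationError("ss must be >= 0")
    return math.sqrt(ss / N)


def compute_aic(N: int, ss: float, v: int) -> float:
    """Akaike Information Criterion N·ln(ss/N) + 2v.

    A perfect fit (ss = 0) returns −inf with a warning so that ranking still
    works; this mirrors fit tables that print RMSE 0.000 for such fits.
    """
    if N <= 0 or v < 1:
        raise ValidationError("need N > 0 and v >= 1")
    if ss < 0:
        raise ValidationError("ss must be >= 0")
    if ss == 0:
        warnings.warn("perfect fit: ss=0 gives AIC=-inf", RuntimeWarning, stacklevel=2)
        return -math.inf
    return N * math.log(ss / N) + 2 * v


def compute_r2(series: TimeSeries, params: ModelParams) -> float:
    """Coefficient of determination 1 − ss/SStot about the observation mean.

    Can be negative for fits worse than the mean; undefined (raises) when the
    observations have zero variance.
    """
    obs = series.concentration
    if len(obs) < 2:
        raise InsufficientDataError("R² needs at least 2 observations")
    sstot = float(np.sum((obs - obs.mean()) ** 2))
    if sstot == 0:
        raise UndefinedStatisticError("R² undefined: zero variance in observations")
    pred = eval_raw(params.model, params_to_vector(params), series.t)
    ss = float(np.sum((obs - pred) ** 2))
    return 1.0 - ss / sstot


# ---------------------------------------------------------------------------
# Bounds and starting points
# ---------------------------------------------------------------------------

def _default_bounds(model: str, t: np.ndarray, obs: np.ndarray) -> tuple:
    """Per-parameter (lower, upper) arrays enclosing all plausible fits."""
    obs_max = float(obs.max())
    # max finite-difference slope on the per-day means (replicates pooled)
    tu = np.unique(t)
    means = np.array([obs[t == x].mean() for x in tu])
    if len(tu) > 1:
        fd = np.diff(means) / np.diff(tu)
        max_slope = float(max(fd.max(), 0.0))
    else:
        max_slope = 0.0
    if max_slope <= 0:
        max_slope = obs_max / max(float(t.max()), 1.0)
    ranges = {
        "rho_max": (1e-6, 2.0 * obs_max),
        "k": (1e-6, 20.0),
        "R_max": (1e-6, 10.0 * max_slope),
        "lag": (0.0, float(t.max())),
        "n": (1e-3, 20.0),
    }
    names = _PARAM_NAMES[model]
    lo = np.array([ranges[p][0] for p in names])
    hi = np.array([ranges[p][1] for p in names])
    return lo, hi, names


def _heuristic_start(model: str, t: np.ndarray, obs: np.ndarray,
                     lo: np.ndarray, hi: np.ndarray) -> np.ndarray:
    """Data-driven initial guess, clipped into the bounded box."""
    obs_max = float(obs.max())
    tu = np.unique(t)
    means = np.array([obs[t == x].mean() for x in tu])
    if len(tu) > 1:
        fd = np.diff(means) / np.diff(tu)
        slope0 = float(max(fd.max(), 1e-9))
    else:
        slope0 = 1e-9
    # first time the mean exceeds 5% of max, as a lag proxy
    above = tu[means > 0.05 * obs_max]
    lag0 = float(above[0]) if len(above) else 0.0
    guesses = {
        "rho_max": obs_max,
        "k": max(slope0 / obs_max, 1e-3),
        "R_max": slope0,
        "lag": lag0,
        "n": 1.0,
    }
    x0 = np.array([guesses[p] for p in _PARAM_NAMES[model]])
    return np.clip(x0, lo, hi)


def _apply_baseline(series: TimeSeries, mode: str) -> TimeSeries:
    if mode == "raw":
        return series
    t0 = series.t.min()
    baseline = float(series.concentration[series.t == t0].mean())
    pts = tuple((t, max(c - baseline, 0.0), r) for t, c, r in series.points)
    return replace(series, points=pts)


# ---------------------------------------------------------------------------
# Fitting
# ---------------------------------------------------------------------------

def fit_model(series: TimeSeries, model: str, config: FitConfig | None = None) -> FitResult:
    """Fit one kinetic model to a series by bounded multi-start least squares.

    The SSE-minimizing parameter vector over ``config.n_starts`` starting
    points (one data-driven heuristic plus Latin-hypercube samples of the
    bounded box, seeded by ``config.seed``) is returned with its statistics.
    Deterministic given (series, config).

    Raises
    ------
    DegenerateSeriesError
        All observed concentrations are zero — there is no signal to fit.
    InsufficientDataError
        Fewer observations than ``v + 1`` or fewer than two distinct times.
    """
    if model not in _N_PARAMS:
        raise ValidationError(f"unknown model {model!r}")
    config = config or FitConfig()
    series = _apply_baseline(series, config.baseline_mode)
    t, obs = series.t, series.concentration
    v = _N_PARAMS[model]
    if obs.max() == 0:
        raise DegenerateSeriesError(
            f"{series.system_id}/{series.analyte}: all concentrations are zero")
    if len(obs) <= v:
        raise InsufficientDataError(
            f"need N > {v} points for {model}, got {len(obs)}")
    if len(np.unique(t)) < 2:
        raise InsufficientDataError("need at least two distinct time points")

    lo, hi, names = _default_bounds(model, t, obs)
    if config.bounds:
        lo, hi = lo.copy(), hi.copy()
        for i, name in enumerate(names):
            if name in config.bounds:
                lo[i], hi[i] = config.bounds[name]

    starts = [_heuristic_start(model, t, obs, lo, hi)]
    n_lhs = config.n_starts - 1
    if n_lhs > 0:
        sampler = qmc.LatinHypercube(d=len(names), seed=config.seed)
        unit = sampler.random(n_lhs)
        starts.extend(qmc.scale(unit, lo, hi))

    def residuals(theta: np.ndarray) -> np.ndarray:
        return eval_raw(model, theta, t) - obs

    best = None
    best_ss = math.inf
    for x0 in starts:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            try:
                sol = least_squares(
                    residuals, x0, bounds=(lo, hi), method="trf",
                    ftol=config.sse_tol, xtol=1e-14, gtol=1e-14,
                    max_nfev=2000)
            except Exception:
                continue
        ss = float(2.0 * sol.cost)
        if ss < best_ss - 1e-300 or (best is None):
            best, best_ss = sol, ss

    if best is None:
        raise NoFitError(f"optimizer failed from every start for {model}")

    params = vector_to_params(model, best.x)
    N = len(obs)
    ss = best_ss
    rmse = compute_rmse(N, ss)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        aic = compute_aic(N, ss, v)
    try:
        r2 = compute_r2(series, params)
    except UndefinedStatisticError:
        r2 = math.nan
    return FitResult(
        model=model, params=params, N=N, v=v, ss=ss, r2=r2, aic=aic,
        rmse=rmse, converged=bool(best.success), n_starts_used=len(starts),
        system_id=series.system_id, analyte=series.analyte)


def rank_models(results: Sequence[FitResult]) -> ModelComparison:
    """Rank fits of one series: ascending AIC, ties by RMSE, then fewer
    parameters, then canonical model order."""
    if len(results) < 2:
        raise MismatchError("ranking needs at least two fit results")
    keys = {(r.system_id, r.analyte) for r in results}
    if len(keys) > 1:
        raise MismatchError(f"results from different series: {sorted(keys)}")
    order = sorted(
        results,
        key=lambda r: (r.aic, r.rmse, r.v, MODEL_ORDER.index(r.model)))
    sid, analyte = next(iter(keys))
    return ModelComparison(
        results=tuple(order),
        ranking=tuple(r.model for r in order),
        best=order[0].model,
        system_id=sid, analyte=analyte)


def fit_all(series: TimeSeries, config: FitConfig | None = None,
            models: Sequence[str] = MODEL_ORDER) -> ModelComparison:
    """Fit every candidate model and rank the successful fits.

    Models that fail (too few points for their parameter count, degenerate
    data, optimizer failure) are recorded in ``failed`` rather than raising,
    mirroring fit tables that print "–" for unfittable cells; if all models
    fail a :class:`NoFitError` is raised.
    """
    results, failed = [], {}
    for model in models:
        try:
            results.append(fit_model(series, model, config))
        except (DegenerateSeriesError, InsufficientDataError, NoFitError) as exc:
            failed[model] = str(exc)
    if not results:
        raise NoFitError(
            f"{series.system_id}/{series.analyte}: no model could be fitted "
            f"({'; '.join(failed.values())})")
    if len(results) == 1:
        only = results[0]
        return ModelComparison(
            results=(only,), ranking=(only.model,), best=only.model,
            failed=failed, system_id=only.system_id, analyte=only.analyte)
    comparison = rank_models(results)
    return replace(comparison, failed=failed)
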