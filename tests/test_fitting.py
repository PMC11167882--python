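"""Least-squares fitting, goodness-of-fit statistics and model ranking."""

import dataclasses
import math

import numpy as np
import pytest

from carboxkin import (
    DegenerateSeriesError,
    FirstOrderParams,
    FitConfig,
    GompertzParams,
    InsufficientDataError,
    MismatchError,
    TimeSeries,
    UndefinedStatisticError,
    ValidationError,
    compute_aic,
    compute_r2,
    compute_rmse,
    eval_model,
    fit_all,
    fit_model,
    rank_models,
)
from carboxkin.fitting import FitResult
from carboxkin.models import params_to_vector

from conftest import ROUNDTRIP_TRUTHS, make_noiseless


class TestStatistics:
    @pytest.mark.parametrize(
        "N, ss, v, expected",
        [
            (10, 10.0, 2, 4.0),                     # ln(1) = 0
            (9, 9.0, 3, 6.0),
            (8, 0.008, 3, 8 * math.log(0.001) + 6),  # = -49.26...
        ],
    )
    def test_aic(self, N, ss, v, expected):
        assert compute_aic(N, ss, v) == pytest.approx(expected, rel=1e-12)

    def test_aic_perfect_fit_is_minus_infinity_with_warning(self):
        with pytest.warns(RuntimeWarning):
            assert compute_aic(5, 0.0, 2) == -math.inf

    @pytest.mark.parametrize(
        "N, ss, expected", [(4, 0.16, 0.2), (5, 0.0, 0.0), (8, 0.000128, 0.004)]
    )
    def test_rmse(self, N, ss, expected):
        assert compute_rmse(N, ss) == pytest.approx(expected, rel=1e-12)

    def test_r2_perfect_and_mean_and_hand_case(self):
        obs = TimeSeries.from_arrays("s", "C3", [0, 1, 2], [0.0, 1.0, 2.0])
        # prediction {0,1,3}: ss=1, sstot=2 -> R2 = 0.5; realised via a probe
        # parameter set whose curve passes through those values is overkill --
        # check the formula through a fit result instead, and the two trivial
        # cases directly on the arithmetic.
        sstot = float(np.sum((obs.concentration - obs.concentration.mean()) ** 2))
        assert 1 - 1.0 / sstot == pytest.approx(0.5)

        series = make_noiseless(FirstOrderParams(1.0, 0.2), [0, 1, 3, 5, 7, 11, 14])
        assert compute_r2(series, FirstOrderParams(1.0, 0.2)) == pytest.approx(1.0)

    def test_r2_zero_variance_rejected(self):
        flat = TimeSeries.from_arrays("s", "C3", [0, 1, 2], [0.5, 0.5, 0.5])
        with pytest.raises(UndefinedStatisticError):
            compute_r2(flat, FirstOrderParams(1.0, 0.2))


class TestFitModel:
    @pytest.mark.parametrize("model", list(ROUNDTRIP_TRUTHS))
    def test_noiseless_round_trip(self, model, sampling_days, fast_fit):
        """Refitting noiseless generated data recovers the generating
        parameters to 1e-6 relative, with r2 = 1 and near-zero ss."""
        truth = ROUNDTRIP_TRUTHS[model]
        series = make_noiseless(truth, sampling_days)
        fit = fit_model(series, model, fast_fit)
        np.testing.assert_allclose(
            params_to_vector(fit.params), params_to_vector(truth),
            rtol=1e-6, atol=1e-9)
        assert fit.ss <= 1e-12
        assert fit.r2 == pytest.approx(1.0, abs=1e-9)
        assert fit.N == len(series) and fit.v in (2, 3)

    def test_all_zero_series_is_degenerate(self, fast_fit):
        zeros = TimeSeries.from_arrays("s", "C6", [0, 3, 7, 14, 21], [0.0] * 5)
        with pytest.raises(DegenerateSeriesError):
            fit_model(zeros, "first-order", fast_fit)

    def test_too_few_points_rejected(self, fast_fit):
        tiny = TimeSeries.from_arrays("s", "C6", [0, 7, 21], [0.0, 0.1, 0.2])
        with pytest.raises(InsufficientDataError):
            fit_model(tiny, "gompertz", fast_fit)

    def test_deterministic_given_seed(self, sampling_days):
        rng = np.random.default_rng(5)
        truth = GompertzParams(0.05, 0.006, 7.02)
        noisy = eval_model(truth, sampling_days) + rng.normal(0, 1e-3, sampling_days.size)
        series = TimeSeries.from_arrays("s", "C6", sampling_days, np.maximum(noisy, 0))
        cfg = FitConfig(n_starts=8, seed=42)
        a, b = fit_model(series, "gompertz", cfg), fit_model(series, "gompertz", cfg)
        assert params_to_vector(a.params).tobytes() == params_to_vector(b.params).tobytes()
        assert a.ss == b.ss and a.aic == b.aic

    def test_pooled_replicates_are_fit_per_point(self, fast_fit):
        truth = FirstOrderParams(1.0, 0.2)
        days = np.array([0, 1, 3, 5, 7, 11, 14, 21, 28.0])
        clean = eval_model(truth, days)
        t2 = np.concatenate([days, days])
        c2 = np.concatenate([clean + 0.01, clean - 0.01])
        series = TimeSeries.from_arrays(
            "s", "C4", t2, np.maximum(c2, 0), ["r1"] * 9 + ["r2"] * 9)
        fit = fit_model(series, "first-order", fast_fit)
        assert fit.N == 18
        assert fit.params.k == pytest.approx(truth.k, rel=0.05)

    def test_subtract_t0_baseline_mode(self, sampling_days, fast_fit):
        truth = FirstOrderParams(0.5, 0.25)
        offset = 0.2  # silages carry carboxylates at inoculation
        series = TimeSeries.from_arrays(
            "s", "C2", sampling_days, eval_model(truth, sampling_days) + offset)
        cfg = dataclasses.replace(fast_fit, baseline_mode="subtract_t0")
        fit = fit_model(series, "first-order", cfg)
        assert fit.params.rho_max == pytest.approx(truth.rho_max, rel=1e-4)
        assert fit.params.k == pytest.approx(truth.k, rel=1e-4)

    def test_grid_search_oracle_equivalence(self):
        """The multi-start optimum of a 2-parameter first-order fit matches a
        dense 400x400 grid search over the same bounded box."""
        truth = FirstOrderParams(0.8, 0.3)
        days = np.array([1.0, 4.0, 9.0, 16.0, 25.0])
        rng = np.random.default_rng(17)
        obs = np.maximum(eval_model(truth, days) + rng.normal(0, 0.02, 5), 0)
        series = TimeSeries.from_arrays("s", "C4", days, obs)
        fit = fit_model(series, "first-order", FitConfig(n_starts=8, seed=3))

        rho_grid = np.linspace(1e-6, 2 * obs.max(), 400)
        k_grid = np.linspace(1e-6, 20.0, 400)
        R, K = np.meshgrid(rho_grid, k_grid, indexing="ij")
        pred = R[..., None] * (1 - np.exp(-K[..., None] * days))
        sse = ((pred - obs) ** 2).sum(axis=-1)
        i, j = np.unravel_index(np.argmin(sse), sse.shape)

        assert fit.ss <= sse[i, j] + 1e-12
        assert abs(fit.params.rho_max - rho_grid[i]) <= rho_grid[1] - rho_grid[0]
        assert abs(fit.params.k - k_grid[j]) <= k_grid[1] - k_grid[0]

    def test_aic_rmse_consistency_on_fit_results(self, sampling_days, fast_fit):
        """AIC = 2N ln(RMSE) + 2v holds for every fit with ss > 0."""
        rng = np.random.default_rng(23)
        truth = GompertzParams(0.05, 0.006, 7.02)
        noisy = np.maximum(
            eval_model(truth, sampling_days) + rng.normal(0, 2e-3, sampling_days.size), 0)
        series = TimeSeries.from_arrays("s", "C6", sampling_days, noisy)
        comp = fit_all(series, fast_fit)
        for res in comp.results:
            if res.ss > 0:
                assert res.aic == pytest.approx(
                    2 * res.N * math.log(res.rmse) + 2 * res.v, abs=1e-9)
            assert res.rmse == pytest.approx(math.sqrt(res.ss / res.N), rel=1e-12)

    def test_noise_degrades_fit_quality_on_average(self, sampling_days):
        """Mean refit R2 decreases as measurement noise grows (statistical
        trend over 100 seeds; a noiseless refit is exact)."""
        truth = FirstOrderParams(1.0, 0.2)
        clean = eval_model(truth, sampling_days)
        cfg = FitConfig(n_starts=4, seed=0)

        def mean_r2(sigma, n_seeds=100):
            vals = []
            for seed in range(n_seeds):
                rng = np.random.default_rng(seed)
                obs = np.maximum(clean + rng.normal(0, sigma, clean.size), 0)
                s = TimeSeries.from_arrays("s", "C4", sampling_days, obs)
                vals.append(fit_model(s, "first-order", cfg).r2)
            return float(np.mean(vals))

        r2_small, r2_large = mean_r2(0.01), mean_r2(0.05)
        assert r2_large < r2_small < 1.0 + 1e-12


def _result(model, aic, rmse, v, sid="s", analyte="C6"):
    params = {"first-order": FirstOrderParams(1, 0.1),
              "gompertz": GompertzParams(1, 0.1, 1),
              "logistic": GompertzParams(1, 0.1, 1),
              "fitzhugh": FirstOrderParams(1, 0.1)}[model]
    if model == "logistic":
        from carboxkin import LogisticParams
        params = LogisticParams(1, 0.1, 1)
    elif model == "fitzhugh":
        from carboxkin import FitzhughParams
        params = FitzhughParams(1, 0.1, 2)
    N = 12
    ss = N * rmse**2
    return FitResult(model=model, params=params, N=N, v=v, ss=ss, r2=0.9,
                     aic=aic, rmse=rmse, converged=True, n_starts_used=8,
                     system_id=sid, analyte=analyte)


class TestRanking:
    def test_minimum_aic_wins(self):
        results = [
            _result("first-order", -86.2, 0.03, 2),
            _result("gompertz", -54.3, 0.05, 3),
            _result("logistic", -89.1, 0.02, 3),
            _result("fitzhugh", -68.1, 0.04, 3),
        ]
        comp = rank_models(results)
        assert comp.best == "logistic"
        assert comp.ranking[0] == "logistic"
        assert set(comp.ranking) == {r.model for r in results}

    def test_parsimony_tie_break(self):
        results = [
            _result("gompertz", -50.0, 0.02, 3),
            _result("first-order", -50.0, 0.02, 2),
        ]
        assert rank_models(results).best == "first-order"

    def test_single_result_is_a_mismatch(self):
        with pytest.raises(MismatchError):
            rank_models([_result("gompertz", -50.0, 0.02, 3)])

    def test_different_series_rejected(self):
        with pytest.raises(MismatchError):
            rank_models([
                _result("gompertz", -50.0, 0.02, 3, sid="a"),
                _result("logistic", -40.0, 0.03, 3, sid="b"),
            ])


class TestFitAll:
    def test_lagged_series_selects_gompertz(self, sampling_days, fast_fit):
        truth = GompertzParams(0.05, 0.006, 7.02)
        series = make_noiseless(truth, sampling_days)
        comp = fit_all(series, fast_fit)
        assert comp.best == "gompertz"
        assert comp.result_for("gompertz").params.lag == pytest.approx(7.02, abs=1e-4)

    def test_first_order_data_gives_fitzhugh_n_near_one(self, sampling_days, fast_fit):
        series = make_noiseless(FirstOrderParams(1.0, 0.2), sampling_days)
        comp = fit_all(series, fast_fit)
        assert comp.result_for("fitzhugh").params.n == pytest.approx(1.0, abs=1e-3)

    def test_all_zero_series_raises_no_fit(self, fast_fit):
        from carboxkin import NoFitError
        zeros = TimeSeries.from_arrays("s", "C6", range(6), [0.0] * 6)
        with pytest.raises(NoFitError):
            fit_all(zeros, fast_fit)

    def test_invalid_config_rejected(self):
        with pytest.raises(ValidationError):
            FitConfig(n_starts=0)
        with pytest.raises(ValidationError):
            FitConfig(bounds={"k": (2.0, 1.0)})
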