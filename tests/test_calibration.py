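"""Unit tests for the pooled least-squares calibration machinery."""

import numpy as np
import pytest

from angiosched import (
    CalibrationProblem,
    FitResult,
    ModelParams,
    ObservedSeries,
    fit,
    objective,
    prefit_control,
    standard_errors,
)
from angiosched.dynamics import GroupSpec


@pytest.fixture(scope="module")
def degenerate_problem(pk_pair, expe2):
    """a = 0 and inert drugs force N == 1 for all time."""
    base = ModelParams(a=0.0, b=0.0, d=0.0, e_txl=0.0, e_beva=0.0, K0=2.0, t_I=8.0)
    data = ObservedSeries("Control", np.array([10.0, 20.0]), np.array([2.0, 3.0]))
    return CalibrationProblem(
        datasets=[data],
        model_id=1,
        groups={"Control": GroupSpec("Control", ())},
        base_params=base,
        pk_cyto=pk_pair[0],
        pk_anti=pk_pair[1],
        free=("K0",),
        rtol=1e-7,
    )


class TestObjective:
    def test_hand_arithmetic_on_flat_model(self, degenerate_problem):
        # N == 1 everywhere, y = (2, 3): J = (2-1)^2 + (3-1)^2 = 5
        assert objective({"K0": 2.0}, degenerate_problem) == pytest.approx(5.0)

    def test_zero_at_generating_parameters(self, pk_pair, expe2, params_m1):
        from angiosched import SynthDesign, generate_growth_data

        data = generate_growth_data(
            SynthDesign(experiment=2, noise_cv=0.0, seed=3, true_params=params_m1),
            model_id=1,
        )
        prob = CalibrationProblem(
            datasets=data,
            model_id=1,
            groups={g.label: g for g in expe2.groups()},
            base_params=params_m1,
            pk_cyto=pk_pair[0],
            pk_anti=pk_pair[1],
            free=("a", "e_txl"),
            rtol=1e-7,
        )
        truth = {"a": params_m1.a, "e_txl": params_m1.e_txl}
        assert objective(truth, prob) < 1e-6
        # local-minimum probe: +/-20% perturbations only increase J
        for name in truth:
            for factor in (0.8, 1.2):
                perturbed = dict(truth, **{name: truth[name] * factor})
                assert objective(perturbed, prob) > objective(truth, prob)

    def test_invariant_to_group_ordering(self, pk_pair, expe2, params_m1):
        from angiosched import SynthDesign, generate_growth_data

        data = generate_growth_data(
            SynthDesign(experiment=2, noise_cv=0.1, seed=4, true_params=params_m1),
            model_id=1,
        )
        kwargs = dict(
            model_id=1,
            groups={g.label: g for g in expe2.groups()},
            base_params=params_m1,
            pk_cyto=pk_pair[0],
            pk_anti=pk_pair[1],
            free=("a",),
            rtol=1e-7,
        )
        forward = CalibrationProblem(datasets=data, **kwargs)
        backward = CalibrationProblem(datasets=data[::-1], **kwargs)
        theta = {"a": params_m1.a}
        assert objective(theta, forward) == pytest.approx(
            objective(theta, backward), rel=1e-12
        )

    def test_simulation_failure_yields_finite_penalty(self, pk_pair):
        base = ModelParams(
            a=2.0, b=0.0, d=0.0, e_txl=0.0, e_beva=0.0, K0=2.0, t_I=8.0
        )
        data = ObservedSeries("Control", np.array([10.0, 20.0]), np.array([2.0, 3.0]))
        prob = CalibrationProblem(
            datasets=[data],
            model_id=1,
            groups={"Control": GroupSpec("Control", ())},
            base_params=base,
            pk_cyto=pk_pair[0],
            pk_anti=pk_pair[1],
            free=("K0",),
            rtol=1e-7,
        )
        value = objective({"K0": 1e290}, prob)  # overflows the Gompertz limit
        assert np.isfinite(value) and value >= 1e12


class TestFit:
    def test_reproducible_bit_for_bit(self, degenerate_problem):
        first = fit(degenerate_problem, {"K0": 2.0}, maxiter=60)
        second = fit(degenerate_problem, {"K0": 2.0}, maxiter=60)
        assert first.theta_hat == second.theta_hat
        assert first.J_min == second.J_min

    def test_missing_init_rejected(self, degenerate_problem):
        with pytest.raises(KeyError, match="init lacks"):
            fit(degenerate_problem, {})


class TestPrefitControl:
    def test_recovers_growth_parameters_from_clean_data(
        self, pk_pair, expe2, params_m1
    ):
        from angiosched import simulate

        truth = params_m1.with_updates(e_txl=0.0, e_beva=0.0)
        times = np.asarray(expe2.obs_times)
        sim = simulate(1, truth, expe2.control(), *pk_pair, (8.0, 52.0), times)
        series = ObservedSeries("Control", times, sim.N)
        est = prefit_control(
            series, 1, truth, *pk_pair,
            init={"a": truth.a * 1.2, "b": truth.b * 0.8,
                  "d": truth.d * 1.2, "K0": truth.K0 * 1.3},
            rtol=1e-7, fatol=1e-12, xatol=1e-8,
        )
        for name in ("a", "b", "d", "K0"):
            assert est[name] == pytest.approx(getattr(truth, name), rel=1e-2)

    def test_flat_data_estimates_no_growth(self, pk_pair, params_m1):
        times = np.array([8.0, 15.0, 22.0, 29.0, 36.0])
        series = ObservedSeries("Control", times, np.ones(5))
        est = prefit_control(
            series, 1, params_m1.with_updates(e_txl=0.0, e_beva=0.0), *pk_pair,
            rtol=1e-7, maxiter=400,
        )
        assert est["a"] < 1e-3

    def test_pure_gompertz_data_keeps_capacity_still(self, pk_pair, expe2):
        """Data from frozen-K growth should not induce capacity drift."""
        from angiosched import simulate

        truth = ModelParams(
            a=0.12, b=0.0, d=0.0, e_txl=0.0, e_beva=0.0, K0=80.0, t_I=8.0
        )
        times = np.asarray(expe2.obs_times)
        sim = simulate(1, truth, expe2.control(), *pk_pair, (8.0, 52.0), times)
        series = ObservedSeries("Control", times, sim.N)
        est = prefit_control(
            series, 1, truth, *pk_pair,
            init={"a": 0.1, "b": 0.01, "d": 0.001, "K0": 60.0},
            rtol=1e-7, fatol=1e-14, xatol=1e-8,
        )
        fitted = truth.with_updates(**est)
        check = simulate(1, fitted, expe2.control(), *pk_pair, (8.0, 52.0), times)
        drift = np.max(np.abs(check.K - fitted.K0)) / fitted.K0
        assert drift < 0.01

    def test_too_few_points_rejected(self, pk_pair, params_m1):
        series = ObservedSeries("Control", np.array([8.0, 10.0, 12.0]), np.ones(3))
        with pytest.raises(ValueError, match="at least 4"):
            prefit_control(series, 1, params_m1, *pk_pair)


def _linear_fit_result(times, y):
    """Closed-form OLS through the origin: y = theta * t."""
    theta = float(times @ y / (times @ times))
    rss = float(np.sum((y - theta * times) ** 2))
    return FitResult(
        theta_hat={"theta": theta},
        free=("theta",),
        J_min=rss,
        converged=True,
        n_obs=times.size,
        n_params=1,
    )


class TestStandardErrors:
    def test_linear_model_oracle(self):
        rng = np.random.default_rng(7)
        times = np.linspace(1.0, 10.0, 12)
        y = 2.5 * times + rng.normal(0.0, 0.8, times.size)
        result = _linear_fit_result(times, y)
        se = standard_errors(
            result, predict_fn=lambda th: th["theta"] * times
        )
        sigma2 = result.J_min / (times.size - 1)
        closed_form = np.sqrt(sigma2 / (times @ times))
        assert se["theta"] == pytest.approx(closed_form, rel=1e-6)

    def test_more_observations_shrink_every_se(self):
        rng = np.random.default_rng(11)

        def se_for(n):
            times = np.linspace(1.0, 10.0, n)
            noise = rng.normal(0.0, 1.0, n)
            y = 2.0 * times + 0.5 * times**2 + noise
            X = np.column_stack([times, times**2])
            beta, rss, *_ = np.linalg.lstsq(X, y, rcond=None)
            result = FitResult(
                theta_hat={"b1": float(beta[0]), "b2": float(beta[1])},
                free=("b1", "b2"),
                J_min=float(rss[0]),
                converged=True,
                n_obs=n,
                n_params=2,
            )
            return standard_errors(
                result,
                predict_fn=lambda th: th["b1"] * times + th["b2"] * times**2,
            )

        sparse, dense = se_for(10), se_for(20)
        assert dense["b1"] < sparse["b1"]
        assert dense["b2"] < sparse["b2"]

    def test_zero_residual_fit_has_zero_se(self):
        times = np.linspace(1.0, 5.0, 8)
        result = _linear_fit_result(times, 3.0 * times)
        se = standard_errors(result, predict_fn=lambda th: th["theta"] * times)
        assert se["theta"] == pytest.approx(0.0, abs=1e-12)

    def test_unidentifiable_parameter_named(self):
        times = np.linspace(1.0, 5.0, 8)
        result = FitResult(
            theta_hat={"slope": 2.0, "ghost": 1.0},
            free=("slope", "ghost"),
            J_min=0.3,
            converged=True,
            n_obs=8,
            n_params=2,
        )
        with pytest.raises(np.linalg.LinAlgError, match="ghost"):
            standard_errors(
                result, predict_fn=lambda th: th["slope"] * times
            )
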